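import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosolv import (
    BoxSpec,
    CycleInput,
    FEPResult,
    LambdaSchedule,
    MCRunConfig,
    PerturbationSample,
    association_free_energy,
    association_from_solvation,
    run_annihilation,
    solvate,
    solvation_free_energy,
    widom_excess_mu,
    zwanzig,
)
from nanosolv.fep import _sw_energy_samples
from nanosolv.forcefield import R_GAS
from nanosolv.mc_engine import MCMoveSpec, run_mc
from nanosolv.structgen import Atom, Structure

T = 298.0
RT = R_GAS * T


class TestZwanzig:
    def test_identical_states_give_zero(self):
        samples = [PerturbationSample(e, e) for e in (-3.0, 0.0, 7.5)]
        assert zwanzig(samples, T) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        gaps=st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        c=st.floats(-100, 100),
    )
    def test_constant_shift_identity(self, gaps, c):
        """Adding a constant to every perturbed energy shifts dG by that constant."""
        g = np.asarray(gaps)
        assert zwanzig(g + c, T) == pytest.approx(zwanzig(g, T) + c, abs=1e-10)

    def test_constant_gap_returns_constant(self):
        assert zwanzig(np.full(17, 3.25), T) == pytest.approx(3.25, abs=1e-12)

    def test_overflow_safe(self):
        assert np.isfinite(zwanzig(np.array([-5000.0, -4000.0]), T))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zwanzig(np.array([]), T)

    def test_two_microstate_enumeration(self):
        """Sampling a two-state system from its exact Boltzmann weights reproduces
        dG = -RT ln(Z_B/Z_A) from the partition functions."""
        ea = np.array([0.0, 1.2])  # reference-state energies
        eb = np.array([0.8, 0.3])  # perturbed-state energies of the same microstates
        za = np.exp(-ea / RT)
        pa = za / za.sum()
        exact = -RT * np.log(np.exp(-eb / RT).sum() / za.sum())

        rng = np.random.default_rng(12)
        n = 40_000
        idx = rng.choice(2, size=n, p=pa)
        gaps = (eb - ea)[idx]
        est = zwanzig(gaps, T)
        blocks = np.array([zwanzig(b, T) for b in np.array_split(gaps, 10)])
        se = blocks.std(ddof=1) / np.sqrt(10)
        assert abs(est - exact) < 3 * max(se, 1e-4)


class TestCycle:
    @pytest.mark.parametrize(
        "drug,tube,complex_,expected",
        [
            (-21.134, -248.2917, -223.0949, -46.3308),
            (-21.7606, -248.2917, -206.97, -63.0823),
        ],
    )
    def test_published_legs_close_the_cycle(self, drug, tube, complex_, expected):
        dg = association_free_energy(CycleInput(drug, tube, complex_))
        assert dg == pytest.approx(expected, abs=1e-4)

    def test_degenerate_identity(self):
        assert association_free_energy(CycleInput(0.0, 0.0, 5.0)) == -5.0

    def test_conventions_agree(self):
        """The annihilation-leg and solvation-convention entry points give the
        same association free energy."""
        d, t, c = -21.134, -248.2917, -223.0949
        assert association_free_energy(CycleInput(d, t, c)) == pytest.approx(
            association_from_solvation(-d, -t, -c), abs=1e-12
        )


class TestSolvationConvention:
    def test_sign_of_solvation_free_energy(self):
        res = FEPResult(
            window_dg=np.array([248.2917]), window_se=np.array([0.0]),
            total=248.2917, total_se=0.0, gas_leg=0.0,
        )
        assert solvation_free_energy(res) == pytest.approx(-248.2917)

    def test_gas_leg_cancels(self):
        res = FEPResult(
            window_dg=np.array([5.0]), window_se=np.array([0.0]),
            total=5.0, total_se=0.0, gas_leg=5.0,
        )
        assert solvation_free_energy(res) == 0.0


def _one_site_solute(epsilon, sigma, charge, where, ff):
    ff.sites.setdefault("probe", None)
    from nanosolv.forcefield import LJSite

    ff.sites["probe"] = LJSite("probe", epsilon, sigma)
    return Structure([Atom("X", where, charge, "probe")], "probe")


class TestAnnihilation:
    def test_ghost_solute_gives_zero(self, ff_small, small_water_state):
        """A solute with no charges and no LJ wells has an exactly flat
        annihilation profile."""
        ghost = Structure([Atom("X", [6.2, 6.2, 6.2], 0.0, "H(W)")], "ghost")
        st = small_water_state.copy()
        st.solute = ghost
        schedule = LambdaSchedule(windows=(1.0, 0.5, 0.0))
        cfg = MCRunConfig(n_equil=1000, n_prod=4000, seed=3, sample_every=100, coord_every=100)
        res = run_annihilation(st, schedule, cfg, ff_small)
        assert res.total == pytest.approx(0.0, abs=max(3 * res.total_se, 1e-9))

    def test_reverse_direction_negates(self, ff_small, equilibrated_water):
        """Growing the probe (0 -> 1) gives the negated annihilation free energy
        within combined statistical error (hysteresis check)."""
        import dataclasses

        ff = dataclasses.replace(ff_small)
        ff.sites = dict(ff_small.sites)
        probe = _one_site_solute(0.15, 2.9, 0.0, [6.2, 6.2, 6.2], ff)
        st = equilibrated_water.copy()
        st.solute = probe

        spec = MCMoveSpec(d_translate=0.30, d_rotate=25.0)
        lams = (1.0, 0.7, 0.4, 0.2, 0.0)
        cfg = MCRunConfig(
            n_equil=20_000, n_prod=150_000, seed=31, sample_every=500, coord_every=500
        )
        res_fwd = run_annihilation(
            st, LambdaSchedule(windows=lams, mode="single"), cfg, ff, move_spec=spec
        )

        # growth direction, assembled from the same public machinery
        alpha = 0.5
        dg_rev = 0.0
        se2 = 0.0
        current = st
        for i in range(len(lams) - 1, 0, -1):  # sample at the lower lambda of each pair
            lam = lams[i]
            c = MCRunConfig(
                n_equil=20_000, n_prod=150_000, seed=31 + 7 * i, sample_every=500, coord_every=500
            )
            traj = run_mc(current, spec, c, ff, lam_elec=lam, lam_vdw=lam, softcore_alpha=alpha)
            current = traj.final_state
            e_here = _sw_energy_samples(traj.coords, st, ff, lam, alpha)
            gaps = _sw_energy_samples(traj.coords, st, ff, lams[i - 1], alpha) - e_here
            dg_rev += zwanzig(gaps, T)
            blocks = np.array([zwanzig(b, T) for b in np.array_split(gaps, 10)])
            se2 += blocks.var(ddof=1) / 10
        combined = 3.0 * np.sqrt(res_fwd.total_se**2 + se2)
        assert abs(res_fwd.total + dg_rev) < combined

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            LambdaSchedule(windows=(0.0, 0.5, 1.0))
        with pytest.raises(ValueError):
            LambdaSchedule(windows=(1.0, 0.5))

    def test_window_additivity_single_window(self, ff_small, small_water_state):
        """With one window the total is that window's increment by construction."""
        ghost = Structure([Atom("X", [6.2, 6.2, 6.2], 0.2, "H(W)")], "ion")
        st = small_water_state.copy()
        st.solute = ghost
        schedule = LambdaSchedule(windows=(1.0, 0.0), mode="single", softcore_alpha=0.5)
        cfg = MCRunConfig(n_equil=500, n_prod=2000, seed=5, sample_every=100, coord_every=100)
        res = run_annihilation(st, schedule, cfg, ff_small)
        assert res.total == pytest.approx(float(res.window_dg.sum()), abs=1e-12)
        assert len(res.window_dg) == 1
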