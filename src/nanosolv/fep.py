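"""Free-energy perturbation: Zwanzig estimator, staged solute annihilation, and the
thermodynamic cycle for drug-carrier association free energies.

The solvation leg is computed by alchemical annihilation: the solute-water coupling
is switched off over a ladder of lambda windows (charges scale linearly, the LJ term
through a soft-core form that removes the end-point singularity), sampling at each
window with the Metropolis engine and estimating each increment with the Zwanzig
exponential-average formula

    dG(A -> B) = -RT ln < exp(-(E_B - E_A)/RT) >_A .

For a rigid solute the gas-phase annihilation leg is identically zero (no
intramolecular energy changes), so dG_solv(A) = dG_gas(A->0) - dG_sol(A->0)
reduces to -dG_sol(A->0).  The association free energy of a drug-tube complex
follows from the cycle of three annihilation legs:

    dG_ass = dG_sol(drug->0) + dG_sol(tube->0) - dG_sol(complex->0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .forcefield import R_GAS, ForceFieldTable, _sw_total
from .mc_engine import MCMoveSpec, MCRunConfig, run_mc
from .structgen import SimulationState

__all__ = [
    "PerturbationSample",
    "LambdaSchedule",
    "FEPResult",
    "CycleInput",
    "zwanzig",
    "run_annihilation",
    "solvation_free_energy",
    "association_free_energy",
    "association_from_solvation",
    "widom_excess_mu",
]


@dataclass(frozen=True)
class PerturbationSample:
    """Reference-state and perturbed-state energy of one sampled configuration."""

    e_ref: float
    e_pert: float


@dataclass
class LambdaSchedule:
    """Coupling ladder for annihilation, ordered from 1 (fully interacting) to 0
    (ghost).  ``double_wide`` evaluates both neighbouring windows from each
    trajectory and averages the two estimates of every increment."""

    windows: Sequence[float] = field(
        default_factory=lambda: (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.0)
    )
    mode: str = "double_wide"
    softcore_alpha: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if len(w) < 2 or w[0] != 1.0 or w[-1] != 0.0 or np.any(np.diff(w) >= 0):
            raise ValueError("windows must decrease strictly from 1 to 0")
        if self.softcore_alpha < 0:
            raise ValueError("softcore_alpha must be >= 0")
        if self.mode not in ("single", "double_wide"):
            raise ValueError("mode must be 'single' or 'double_wide'")


@dataclass
class FEPResult:
    """Per-window free-energy increments (kcal/mol) with block-averaged standard
    errors; ``total`` is the full annihilation leg dG_sol(A->0).  The gas-phase leg
    is carried explicitly (zero for rigid solutes) so the sign convention of the
    solvation free energy stays auditable."""

    window_dg: np.ndarray
    window_se: np.ndarray
    total: float
    total_se: float
    gas_leg: float = 0.0
    n_samples_per_window: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.window_dg)) - self.total) > 1e-9:
            raise ValueError("total must equal the sum of window increments")


@dataclass
class CycleInput:
    """The three annihilation legs of the association cycle (kcal/mol)."""

    dG_sol_drug: float
    dG_sol_tube: float
    dG_sol_complex: float


def zwanzig(
    samples: Union[Iterable[PerturbationSample], np.ndarray],
    temperature: float = 298.0,
) -> float:
    """Zwanzig free-energy estimate from energy gaps sampled in the reference state.

    Accepts either PerturbationSample records or an array of gaps (e_pert - e_ref).
    Computed with log-sum-exp, so arbitrarily large gaps cannot overflow.
    """
    gaps = _as_gaps(samples)
    if gaps.size == 0:
        raise ValueError("zwanzig needs at least one sample")
    rt = R_GAS * temperature
    return float(-rt * (logsumexp(-gaps / rt) - np.log(gaps.size)))


def _as_gaps(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        gaps = samples.astype(float).ravel()
    else:
        items = list(samples)
        if items and isinstance(items[0], PerturbationSample):
            gaps = np.array([s.e_pert - s.e_ref for s in items], dtype=float)
        else:
            gaps = np.asarray(items, dtype=float).ravel()
    if not np.all(np.isfinite(gaps)):
        raise ValueError("non-finite energy gap in sample set")
    return gaps


def _block_se(gaps: np.ndarray, temperature: float, n_blocks: int = 10) -> float:
    """Standard error of the Zwanzig estimate by block averaging."""
    if len(gaps) < 2 * n_blocks:
        return float("nan")
    blocks = np.array_split(gaps, n_blocks)
    vals = np.array([zwanzig(b, temperature) for b in blocks])
    return float(vals.std(ddof=1) / np.sqrt(n_blocks))


def _ess_fraction(gaps: np.ndarray, temperature: float) -> float:
    """Effective sample size fraction of the exponential average (Kish)."""
    w = -gaps / (R_GAS * temperature)
    w = np.exp(w - w.max())
    return float(w.sum() ** 2 / (len(w) * (w * w).sum()))


def _sw_energy_samples(
    frames: np.ndarray,
    state: SimulationState,
    ff: ForceFieldTable,
    lam: float,
    alpha: float,
) -> np.ndarray:
    """Solute-water energy of every stored frame at coupling ``lam``."""
    spos, sq, seps, ssig = ff.solute_arrays(state.solute)
    wm = ff.water
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        e, v = _sw_total(
            np.ascontiguousarray(frame), spos, sq, seps, ssig, state.box_edge,
            wm.q_o, wm.q_h, wm.epsilon_o, wm.sigma_o, ff.coulomb_constant,
            lam, lam, alpha,
        )
        out[k] = e + v
    return out


def run_annihilation(
    state: SimulationState,
    schedule: LambdaSchedule,
    mc_config: MCRunConfig,
    ff: ForceFieldTable,
    move_spec: Optional[MCMoveSpec] = None,
) -> FEPResult:
    """Annihilate the solute over the lambda ladder and return dG_sol(A->0).

    At each window lambda_i an MC trajectory is generated with the solute-water
    coupling at lambda_i; stored frames are re-scored at the neighbouring windows
    and each increment is estimated by the Zwanzig formula (both directions are
    combined in double-wide mode).  Windows are warm-started: each run begins
    from the previous window's final configuration, so the per-window
    equilibration only has to relax the small coupling change.  A warning is
    issued when a window's exponential average rests on fewer than 10% effective
    samples.
    """
    if state.solute is None:
        raise ValueError("state has no solute to annihilate")
    if mc_config.coord_every < 1:
        raise ValueError("mc_config.coord_every must be set: frames drive the estimator")
    spec = move_spec or MCMoveSpec()
    lams = np.asarray(schedule.windows, dtype=float)
    alpha = schedule.softcore_alpha
    n_win = len(lams) - 1
    temperature = mc_config.temperature

    fwd = np.full(n_win, np.nan)  # dG(lam_i -> lam_{i+1}) sampled at lam_i
    bwd = np.full(n_win, np.nan)  # same increment sampled at lam_{i+1}
    fwd_se = np.full(n_win, np.nan)
    bwd_se = np.full(n_win, np.nan)
    n_samp = 0
    current = state

    for i, lam in enumerate(lams):
        need_fwd = i < n_win
        need_bwd = schedule.mode == "double_wide" and i > 0
        if not (need_fwd or need_bwd):
            continue
        cfg = MCRunConfig(
            n_equil=mc_config.n_equil,
            n_prod=mc_config.n_prod,
            temperature=temperature,
            seed=(mc_config.seed + 1013 * i) % (2**31 - 2),
            sample_every=mc_config.sample_every,
            coord_every=mc_config.coord_every,
            refresh_every=mc_config.refresh_every,
        )
        traj = run_mc(current, spec, cfg, ff, lam_elec=lam, lam_vdw=lam, softcore_alpha=alpha)
        current = traj.final_state
        frames = traj.coords
        n_samp = len(frames)
        e_here = _sw_energy_samples(frames, state, ff, lam, alpha)
        if need_fwd:
            gaps = _sw_energy_samples(frames, state, ff, lams[i + 1], alpha) - e_here
            fwd[i] = zwanzig(gaps, temperature)
            fwd_se[i] = _block_se(gaps, temperature)
            if _ess_fraction(gaps, temperature) < 0.10:
                warnings.warn(
                    f"window {lam:.3g}->{lams[i + 1]:.3g}: effective sample size "
                    "below 10% of samples; increment is poorly conditioned",
                    stacklevel=2,
                )
        if need_bwd:
            gaps = _sw_energy_samples(frames, state, ff, lams[i - 1], alpha) - e_here
            bwd[i - 1] = -zwanzig(gaps, temperature)
            bwd_se[i - 1] = _block_se(gaps, temperature)

    if schedule.mode == "double_wide":
        window_dg = np.where(np.isnan(bwd), fwd, 0.5 * (fwd + bwd))
        window_se = np.where(
            np.isnan(bwd_se), fwd_se, 0.5 * np.sqrt(fwd_se**2 + bwd_se**2)
        )
    else:
        window_dg = fwd
        window_se = fwd_se
    total = float(np.sum(window_dg))
    total_se = float(np.sqrt(np.nansum(window_se**2)))
    return FEPResult(
        window_dg=window_dg,
        window_se=window_se,
        total=total,
        total_se=total_se,
        gas_leg=0.0,
        n_samples_per_window=n_samp,
        seed=mc_config.seed,
    )


def solvation_free_energy(result: FEPResult) -> float:
    """dG_solv(A) = dG_gas(A->0) - dG_sol(A->0); the gas leg is zero for rigid
    solutes, so this is simply the negated annihilation leg."""
    return result.gas_leg - result.total


def association_free_energy(c: CycleInput) -> float:
    """Association free energy from the three annihilation legs:
    dG_ass = dG_sol(drug->0) + dG_sol(tube->0) - dG_sol(complex->0)."""
    return c.dG_sol_drug + c.dG_sol_tube - c.dG_sol_complex


def association_from_solvation(
    dG_solv_drug: float, dG_solv_tube: float, dG_solv_complex: float
) -> float:
    """Equivalent entry point in the solvation convention:
    dG_ass = dG_solv(complex) - dG_solv(drug) - dG_solv(tube)."""
    return dG_solv_complex - dG_solv_drug - dG_solv_tube


def widom_excess_mu(
    frames: np.ndarray,
    box_edge: float,
    ff: ForceFieldTable,
    epsilon: float,
    sigma: float,
    charge: float = 0.0,
    temperature: float = 298.0,
    n_insertions: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Widom test-particle estimate of a solute's excess chemical potential.

    Inserts a single LJ/point-charge site at random positions in each stored
    pure-water frame: mu_ex = -RT ln < exp(-dU/RT) >.  Returns (mu_ex, standard
    error over frames).  Serves as an independent cross-check of the annihilation
    route for a one-site solute.
    """
    rng = np.random.default_rng(seed)
    wm = ff.water
    rt = R_GAS * temperature
    sq = np.array([charge])
    seps = np.array([epsilon])
    ssig = np.array([sigma])
    frame_log = np.empty(len(frames))
    for k, frame in enumerate(frames):
        frame_c = np.ascontiguousarray(frame)
        du = np.empty(n_insertions)
        for m in range(n_insertions):
            spos = rng.uniform(0.0, box_edge, size=(1, 3))
            e, v = _sw_total(
                frame_c, spos, sq, seps, ssig, box_edge,
                wm.q_o, wm.q_h, wm.epsilon_o, wm.sigma_o, ff.coulomb_constant,
                1.0, 1.0, 0.0,
            )
            du[m] = e + v
        frame_log[k] = logsumexp(-du / rt) - np.log(n_insertions)
    # average the Boltzmann factor over all frames, then take the log
    mu = float(-rt * (logsumexp(frame_log) - np.log(len(frames))))
    # frames are serially correlated: block the per-frame estimates (10 blocks)
    n_blocks = min(10, max(2, len(frames) // 2))
    blocks = np.array(
        [-rt * (logsumexp(b) - np.log(len(b))) for b in np.array_split(frame_log, n_blocks)]
    )
    se = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
    return mu, se
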