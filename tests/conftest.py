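import numpy as np
import pytest

from nanosolv import BoxSpec, ForceFieldTable, MCMoveSpec, MCRunConfig, run_mc, solvate


@pytest.fixture(scope="session")
def ff():
    return ForceFieldTable.default()


@pytest.fixture(scope="session")
def ff_small(ff):
    """Registry with a cutoff suited to ~12 A boxes (cutoff <= half edge)."""
    import dataclasses

    return dataclasses.replace(ff, cutoff=6.0)


@pytest.fixture(scope="session")
def small_water_state():
    """A 12.4 A box of 63 waters, freshly seeded (unequilibrated)."""
    return solvate(None, BoxSpec(edge=12.4), seed=11)


@pytest.fixture(scope="session")
def equilibrated_water(small_water_state, ff_small):
    """The same box after a short Metropolis equilibration."""
    traj = run_mc(
        small_water_state,
        MCMoveSpec(),
        MCRunConfig(n_equil=40_000, n_prod=10_000, seed=5, sample_every=500),
        ff_small,
    )
    return traj.final_state


def brute_force_total(state, ff, cutoff=np.inf):
    """Independent all-pairs reference energy for small states.

    Implements the stated conventions directly with plain numpy loops: water-water
    pairs use an O-O molecule-centre minimum-image shift and cutoff; solute-water
    site pairs use per-pair minimum image with no cutoff; LJ sites combined by
    Lorentz-Berthelot.
    """
    wm = ff.water
    L = state.box_edge
    qs = np.array([wm.q_o, wm.q_h, wm.q_h])
    ww = 0.0
    n = state.n_water
    for i in range(n):
        for j in range(i + 1, n):
            doo = state.waters[j][0] - state.waters[i][0]
            shift = -L * np.round(doo / L)
            if np.linalg.norm(doo + shift) > cutoff:
                continue
            for a in range(3):
                for b in range(3):
                    r = np.linalg.norm(state.waters[j][b] + shift - state.waters[i][a])
                    ww += ff.coulomb_constant * qs[a] * qs[b] / r
                    if a == 0 and b == 0:
                        sr6 = (wm.sigma_o / r) ** 6
                        ww += 4 * wm.epsilon_o * (sr6**2 - sr6)
    elec = vdw = 0.0
    if state.solute is not None:
        spos, sq, seps, ssig = ff.solute_arrays(state.solute)
        for w in state.waters:
            for k in range(len(spos)):
                eps = np.sqrt(seps[k] * wm.epsilon_o)
                sig = 0.5 * (ssig[k] + wm.sigma_o)
                for a in range(3):
                    d = w[a] - spos[k]
                    d -= L * np.round(d / L)
                    r = np.linalg.norm(d)
                    elec += ff.coulomb_constant * sq[k] * qs[a] / r
                    if a == 0 and eps > 0:
                        sr6 = (sig / r) ** 6
                        vdw += 4 * eps * (sr6**2 - sr6)
    return ww + elec + vdw, elec, vdw, ww
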