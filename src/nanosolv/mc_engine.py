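"""Canonical-ensemble Metropolis Monte Carlo over rigid waters around a fixed solute.

One cycle: pick a water uniformly at random, translate it by a per-axis uniform
displacement and rotate it by a uniform angle about a random axis through its
oxygen, wrap into the periodic box, and accept with probability
min(1, exp(-dE/RT)).  Energies are maintained by local updates (only the moved
molecule's interactions are recomputed) with a periodic full refresh to bound
floating-point drift.

Random-draw order per cycle is frozen for reproducibility: molecule index,
translation (x, y, z), rotation axis (three normals), rotation angle, acceptance
uniform (always drawn, even for downhill moves).  A fixed seed therefore yields a
bit-identical trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .forcefield import (
    R_GAS,
    EnergyBreakdown,
    ForceFieldTable,
    _sw_energy_water,
    _sw_total,
    _ww_energy_one,
    _ww_total,
    total_energy,
)
from .structgen import SimulationState

__all__ = [
    "MCMoveSpec",
    "MCRunConfig",
    "Trajectory",
    "propose_move",
    "metropolis_accept",
    "delta_energy_local",
    "run_mc",
]


@dataclass
class MCMoveSpec:
    """Move amplitudes: max per-axis translation (A) and max rotation (degrees)."""

    d_translate: float = 0.13
    d_rotate: float = 10.0
    target_acceptance: float = 0.5

    def __post_init__(self) -> None:
        if self.d_translate < 0:
            raise ValueError("d_translate must be >= 0")
        if not (0 <= self.d_rotate <= 180):
            raise ValueError("d_rotate must lie in [0, 180] degrees")


@dataclass
class MCRunConfig:
    """Run protocol: equilibration/production lengths (configurations), temperature,
    seed, and sampling strides.  ``coord_every`` > 0 additionally stores thinned
    water coordinates (needed for structural analysis and free-energy gaps)."""

    n_equil: int = 0
    n_prod: int = 0
    temperature: float = 298.0
    seed: int = 0
    sample_every: int = 100
    coord_every: int = 0
    refresh_every: int = 100_000

    def __post_init__(self) -> None:
        if self.n_equil < 0 or self.n_prod < 0:
            raise ValueError("configuration counts must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sample_every < 1 or self.refresh_every < 1:
            raise ValueError("strides must be >= 1")


@dataclass
class Trajectory:
    """Production-phase record: energy series (columns total, E_soln, elec, vdW,
    water-water), optional thinned water coordinates, and acceptance statistics."""

    energies: np.ndarray  # (n_samples, 5)
    coords: Optional[np.ndarray]  # (n_frames, N, 3, 3) or None
    acceptance: float
    n_attempted: int
    n_accepted: int
    final_state: SimulationState
    equil_acceptance: float = float("nan")

    def mean_breakdown(self) -> EnergyBreakdown:
        if len(self.energies) == 0:
            raise ValueError("empty energy series")
        m = self.energies.mean(axis=0)
        return EnergyBreakdown(
            total=float(m[0]),
            solute_water=float(m[1]),
            electrostatic_in_soln=float(m[2]),
            vdw_in_soln=float(m[3]),
            water_water=float(m[4]),
        )


# ---------------------------------------------------------------------------
# Elementary move machinery (python surface, unit-testable)
# ---------------------------------------------------------------------------


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def propose_move(
    state: SimulationState, spec: MCMoveSpec, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Draw one trial move: uniformly chosen water, per-axis uniform translation in
    [-d, d], rotation by a uniform angle in [-theta, theta] about a random axis
    through the O atom.  Coordinates are wrapped so O lies inside the box."""
    if state.n_water < 1:
        raise ValueError("state has no waters to move")
    i = int(rng.integers(state.n_water))
    trans = rng.uniform(-spec.d_translate, spec.d_translate, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(-spec.d_rotate, spec.d_rotate))
    w = state.waters[i]
    R = _rotation_matrix(axis, angle)
    new = (w - w[0]) @ R.T + w[0] + trans
    wrap = np.floor(new[0] / state.box_edge) * state.box_edge
    return i, new - wrap


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/RT))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return float(rng.random()) < math.exp(-delta_e / (R_GAS * temperature))


def delta_energy_local(
    state: SimulationState,
    water_index: int,
    new_coordinates: np.ndarray,
    ff: ForceFieldTable,
    lam_elec: float = 1.0,
    lam_vdw: float = 1.0,
    softcore_alpha: float = 0.0,
) -> float:
    """E(after) - E(before) from only the moved molecule's interactions; by the
    pairwise additivity of the potential this equals the full total-energy
    difference."""
    wm = ff.water
    waters = np.ascontiguousarray(state.waters)
    w_new = np.ascontiguousarray(np.asarray(new_coordinates, dtype=float))
    args = (state.box_edge, ff.cutoff**2, wm.q_o, wm.q_h, wm.epsilon_o, wm.sigma_o, ff.coulomb_constant)
    e_old = _ww_energy_one(water_index, waters, *args)
    trial = waters.copy()
    trial[water_index] = w_new
    e_new = _ww_energy_one(water_index, trial, *args)
    if state.solute is not None:
        spos, sq, seps, ssig = ff.solute_arrays(state.solute)
        sw_args = (
            spos, sq, seps, ssig, state.box_edge, wm.q_o, wm.q_h, wm.epsilon_o,
            wm.sigma_o, ff.coulomb_constant, lam_elec, lam_vdw, softcore_alpha,
        )
        eo, vo = _sw_energy_water(waters[water_index], *sw_args)
        en, vn = _sw_energy_water(w_new, *sw_args)
        e_old += eo + vo
        e_new += en + vn
    return float(e_new - e_old)


# ---------------------------------------------------------------------------
# Compiled main loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mc_loop(
    waters,
    spos,
    sq,
    seps,
    ssig,
    has_solute,
    box,
    cutoff2,
    q_o,
    q_h,
    eps_o,
    sig_o,
    kc,
    lam_e,
    lam_v,
    alpha,
    d_trans,
    d_rot,
    rt,
    n_steps,
    sample_every,
    coord_every,
    refresh_every,
    seed,
):
    """Metropolis loop with running component energies and periodic full refresh.

    Returns (n_accepted, energy samples, coordinate frames).  Energy sample columns:
    total, E_soln, elec, vdW, water-water.
    """
    np.random.seed(seed)
    n = waters.shape[0]

    e_ww = _ww_total(waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
    e_el = 0.0
    e_vd = 0.0
    if has_solute:
        e_el, e_vd = _sw_total(
            waters, spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
        )

    n_samples = n_steps // sample_every if sample_every > 0 else 0
    energies = np.empty((n_samples, 5))
    n_frames = n_steps // coord_every if coord_every > 0 else 0
    frames = np.empty((n_frames, n, 3, 3))

    old = np.empty((3, 3))
    new = np.empty((3, 3))
    n_accept = 0
    i_sample = 0
    i_frame = 0

    for step in range(n_steps):
        i = np.random.randint(0, n)
        for a in range(3):
            for b in range(3):
                old[a, b] = waters[i, a, b]

        # trial move: rotate about O, then translate, then wrap O into the box
        tx = np.random.uniform(-d_trans, d_trans)
        ty = np.random.uniform(-d_trans, d_trans)
        tz = np.random.uniform(-d_trans, d_trans)
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        ax, ay, az = ax / norm, ay / norm, az / norm
        ang = np.random.uniform(-d_rot, d_rot)
        c = math.cos(ang)
        s = math.sin(ang)
        C = 1.0 - c
        ox, oy, oz = old[0, 0], old[0, 1], old[0, 2]
        for a in range(3):
            px = old[a, 0] - ox
            py = old[a, 1] - oy
            pz = old[a, 2] - oz
            rx = (c + ax * ax * C) * px + (ax * ay * C - az * s) * py + (ax * az * C + ay * s) * pz
            ry = (ay * ax * C + az * s) * px + (c + ay * ay * C) * py + (ay * az * C - ax * s) * pz
            rz = (az * ax * C - ay * s) * px + (az * ay * C + ax * s) * py + (c + az * az * C) * pz
            new[a, 0] = rx + ox + tx
            new[a, 1] = ry + oy + ty
            new[a, 2] = rz + oz + tz
        wx = math.floor(new[0, 0] / box) * box
        wy = math.floor(new[0, 1] / box) * box
        wz = math.floor(new[0, 2] / box) * box
        for a in range(3):
            new[a, 0] -= wx
            new[a, 1] -= wy
            new[a, 2] -= wz

        e_ww_old = _ww_energy_one(i, waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
        e_el_old = 0.0
        e_vd_old = 0.0
        e_el_new = 0.0
        e_vd_new = 0.0
        if has_solute:
            e_el_old, e_vd_old = _sw_energy_water(
                waters[i], spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
            )
        for a in range(3):
            for b in range(3):
                waters[i, a, b] = new[a, b]
        e_ww_new = _ww_energy_one(i, waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
        if has_solute:
            e_el_new, e_vd_new = _sw_energy_water(
                waters[i], spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
            )

        de = (e_ww_new - e_ww_old) + (e_el_new - e_el_old) + (e_vd_new - e_vd_old)
        u = np.random.uniform(0.0, 1.0)  # always drawn: frozen stream layout
        if de <= 0.0 or u < math.exp(-de / rt):
            n_accept += 1
            e_ww += e_ww_new - e_ww_old
            e_el += e_el_new - e_el_old
            e_vd += e_vd_new - e_vd_old
        else:
            for a in range(3):
                for b in range(3):
                    waters[i, a, b] = old[a, b]

        if (step + 1) % refresh_every == 0:
            e_ww = _ww_total(waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
            if has_solute:
                e_el, e_vd = _sw_total(
                    waters, spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
                )

        if sample_every > 0 and (step + 1) % sample_every == 0 and i_sample < n_samples:
            e_sol = e_el + e_vd
            energies[i_sample, 0] = e_ww + e_sol
            energies[i_sample, 1] = e_sol
            energies[i_sample, 2] = e_el
            energies[i_sample, 3] = e_vd
            energies[i_sample, 4] = e_ww
            i_sample += 1
        if coord_every > 0 and (step + 1) % coord_every == 0 and i_frame < n_frames:
            frames[i_frame] = waters
            i_frame += 1

    return n_accept, energies, frames


def run_mc(
    state: SimulationState,
    spec: MCMoveSpec,
    config: MCRunConfig,
    ff: ForceFieldTable,
    lam_elec: float = 1.0,
    lam_vdw: float = 1.0,
    softcore_alpha: float = 0.0,
) -> Trajectory:
    """Equilibrate then sample a solvated state; returns the production trajectory.

    The input state is not modified.  Equilibration and production draw from two
    stream segments seeded ``seed`` and ``seed + 1`` (kept below 2^31), so a fixed
    config seed gives a bit-identical trajectory.  Raises if the starting
    configuration has a non-finite energy (initial clash).
    """
    wm = ff.water
    waters = np.ascontiguousarray(state.waters.copy())
    if state.solute is not None:
        spos, sq, seps, ssig = ff.solute_arrays(state.solute)
        has_solute = True
    else:
        spos = np.zeros((1, 3))
        sq = np.zeros(1)
        seps = np.zeros(1)
        ssig = np.zeros(1)
        has_solute = False

    start = total_energy(state, ff, lam_elec, lam_vdw, softcore_alpha)
    if not np.isfinite(start.total):
        raise ValueError("non-finite starting energy: initial configuration has a clash")

    common = dict(
        spos=np.ascontiguousarray(spos),
        sq=np.ascontiguousarray(sq),
        seps=np.ascontiguousarray(seps),
        ssig=np.ascontiguousarray(ssig),
        has_solute=has_solute,
        box=state.box_edge,
        cutoff2=ff.cutoff**2,
        q_o=wm.q_o,
        q_h=wm.q_h,
        eps_o=wm.epsilon_o,
        sig_o=wm.sigma_o,
        kc=ff.coulomb_constant,
        lam_e=lam_elec,
        lam_v=lam_vdw,
        alpha=softcore_alpha,
        d_trans=spec.d_translate,
        d_rot=math.radians(spec.d_rotate),
        rt=R_GAS * config.temperature,
        refresh_every=config.refresh_every,
    )
    seed0 = config.seed % (2**31 - 2)
    equil_acc = float("nan")
    if config.n_equil > 0:
        na, _, _ = _mc_loop(
            waters, n_steps=config.n_equil, sample_every=0, coord_every=0, seed=seed0, **common
        )
        equil_acc = na / config.n_equil
    n_accept, energies, frames = _mc_loop(
        waters,
        n_steps=config.n_prod,
        sample_every=config.sample_every,
        coord_every=config.coord_every,
        seed=seed0 + 1,
        **common,
    )
    final = SimulationState(
        solute=None if state.solute is None else state.solute.copy(),
        waters=waters,
        box_edge=state.box_edge,
        temperature=config.temperature,
    )
    return Trajectory(
        energies=energies,
        coords=frames if config.coord_every > 0 else None,
        acceptance=(n_accept / config.n_prod) if config.n_prod else 0.0,
        n_attempted=config.n_prod,
        n_accepted=n_accept,
        final_state=final,
        equil_acceptance=equil_acc,
    )
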