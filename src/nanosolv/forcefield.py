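"""Pairwise nonbonded energetics.

Water-water interactions use a rigid three-site model (one Lennard-Jones site and a
point charge on O, point charges on H).  Solute-water interactions are
Lennard-Jones + Coulomb with per-site parameters combined by the Lorentz-Berthelot
rule.  All bodies are rigid, so the total potential energy is purely intermolecular:

    E_total = E_solute-water + E_water-water
    E_solute-water = E_electrostatic + E_vdW

Conventions: energies in kcal/mol, distances in Angstrom, charges in elementary
charge units.  Water-water pairs use a molecule-centre (O-O) spherical cutoff with
minimum-image periodic boundaries; solute-water sums run over all pairs with
per-pair minimum image, because the solute (a ~22 A nanotube) is larger than any
sensible cutoff sphere.

The hot kernels are numba-compiled and shared verbatim between total-energy
evaluation and the Monte Carlo engine's local updates, so the two paths are
arithmetically consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .structgen import SimulationState, Structure

__all__ = [
    "K_COULOMB",
    "R_GAS",
    "LJSite",
    "WaterModel",
    "ForceFieldTable",
    "EnergyBreakdown",
    "combine_lj",
    "ac_from_epsilon_sigma",
    "epsilon_sigma_from_ac",
    "pair_energy",
    "interaction_energy",
    "total_energy",
]

# Coulomb constant, kcal*A/(mol*e^2)
K_COULOMB = 332.06
# gas constant, kcal/(mol*K)
R_GAS = 1.98720425e-3


@dataclass(frozen=True)
class LJSite:
    """One Lennard-Jones site type: well depth epsilon (kcal/mol), diameter sigma (A),
    and optionally a default partial charge."""

    label: str
    epsilon: float
    sigma: float
    charge_default: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.sigma < 0:
            raise ValueError("epsilon and sigma must be non-negative")


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site water parameters: LJ on O only, charges on O and both H."""

    epsilon_o: float = 0.1521
    sigma_o: float = 3.1507
    q_o: float = -0.834
    q_h: float = 0.417

    def __post_init__(self) -> None:
        if abs(self.q_o + 2.0 * self.q_h) > 1e-9:
            raise ValueError("water charges must sum to zero per molecule")


@dataclass
class ForceFieldTable:
    """Registry of LJ site types plus the water block, Coulomb constant and cutoff."""

    sites: dict[str, LJSite]
    water: WaterModel = field(default_factory=WaterModel)
    coulomb_constant: float = K_COULOMB
    cutoff: float = 9.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @classmethod
    def default(cls) -> "ForceFieldTable":
        """Load the packaged LJ table (nanotube and drug sites) and append the
        water-oxygen site 'O(W)', which also serves as the fallback for solute
        oxygens absent from the table."""
        with resources.files("nanosolv.tables").joinpath("table1_lj.csv").open() as fh:
            tab = pd.read_csv(fh)
        sites = {
            str(r.label): LJSite(str(r.label), float(r.epsilon), float(r.sigma))
            for r in tab.itertuples()
        }
        wm = WaterModel()
        sites["O(W)"] = LJSite("O(W)", wm.epsilon_o, wm.sigma_o, wm.q_o)
        sites["H(W)"] = LJSite("H(W)", 0.0, 0.0, wm.q_h)
        return cls(sites=sites, water=wm)

    def lookup(self, label: str) -> LJSite:
        try:
            return self.sites[label]
        except KeyError:
            raise KeyError(f"LJ label {label!r} not in force-field registry") from None

    def solute_arrays(self, s: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flatten a structure into (positions, charges, epsilons, sigmas) arrays."""
        eps = np.array([self.lookup(lbl).epsilon for lbl in s.lj_labels])
        sig = np.array([self.lookup(lbl).sigma for lbl in s.lj_labels])
        return s.positions, s.charges, eps, sig


@dataclass
class EnergyBreakdown:
    """Decomposed potential energy (kcal/mol) mirroring the hydration-table layout:
    the solute-water term splits into its electrostatic and van der Waals parts."""

    total: float
    solute_water: float
    water_water: float
    electrostatic_in_soln: float
    vdw_in_soln: float

    def __post_init__(self) -> None:
        if abs(self.electrostatic_in_soln + self.vdw_in_soln - self.solute_water) > 1e-6:
            raise ValueError("elec + vdW must equal the solute-water term")
        if abs(self.solute_water + self.water_water - self.total) > 1e-6:
            raise ValueError("solute-water + water-water must equal the total")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def combine_lj(site_i: LJSite, site_j: LJSite) -> tuple[float, float]:
    """Lorentz-Berthelot mixing: geometric mean of epsilon, arithmetic mean of sigma."""
    return math.sqrt(site_i.epsilon * site_j.epsilon), 0.5 * (site_i.sigma + site_j.sigma)


def ac_from_epsilon_sigma(epsilon: float, sigma: float) -> tuple[float, float]:
    """Convert (epsilon, sigma) to the A/r^12 - C/r^6 parametrisation:
    A = 4*eps*sigma^12, C = 4*eps*sigma^6."""
    return 4.0 * epsilon * sigma**12, 4.0 * epsilon * sigma**6


def epsilon_sigma_from_ac(A: float, C: float) -> tuple[float, float]:
    """Inverse of :func:`ac_from_epsilon_sigma`; requires A, C > 0."""
    if A <= 0 or C <= 0:
        raise ValueError("A and C must be positive to invert")
    sigma = (A / C) ** (1.0 / 6.0)
    return C * C / (4.0 * A), sigma


def pair_energy(
    r: float,
    epsilon_ij: float,
    sigma_ij: float,
    qi: float = 0.0,
    qj: float = 0.0,
    k_coulomb: float = K_COULOMB,
) -> float:
    """LJ + Coulomb energy of one site pair at separation r (A)."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6) + k_coulomb * qi * qj / r


# ---------------------------------------------------------------------------
# Numba kernels (shared by total energies and the MC engine)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mic(d: float, box: float) -> float:
    return d - box * round(d / box)


@njit(cache=True)
def _ww_pair(w1, w2, box, cutoff2, q_o, q_h, eps_o, sig_o, kc):
    """Energy of one water pair; molecule-centre (O-O) minimum image and cutoff."""
    sx = _mic(w2[0, 0] - w1[0, 0], box) - (w2[0, 0] - w1[0, 0])
    sy = _mic(w2[0, 1] - w1[0, 1], box) - (w2[0, 1] - w1[0, 1])
    sz = _mic(w2[0, 2] - w1[0, 2], box) - (w2[0, 2] - w1[0, 2])
    dx = w2[0, 0] + sx - w1[0, 0]
    dy = w2[0, 1] + sy - w1[0, 1]
    dz = w2[0, 2] + sz - w1[0, 2]
    if dx * dx + dy * dy + dz * dz > cutoff2:
        return 0.0
    e = 0.0
    for a in range(3):
        qa = q_o if a == 0 else q_h
        for b in range(3):
            qb = q_o if b == 0 else q_h
            px = w2[b, 0] + sx - w1[a, 0]
            py = w2[b, 1] + sy - w1[a, 1]
            pz = w2[b, 2] + sz - w1[a, 2]
            r2 = px * px + py * py + pz * pz
            r = math.sqrt(r2)
            e += kc * qa * qb / r
            if a == 0 and b == 0:
                sr6 = (sig_o * sig_o / r2) ** 3
                e += 4.0 * eps_o * (sr6 * sr6 - sr6)
    return e


@njit(cache=True)
def _ww_energy_one(i, waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc):
    """Interaction of water i with all other waters."""
    e = 0.0
    for j in range(waters.shape[0]):
        if j != i:
            e += _ww_pair(waters[i], waters[j], box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
    return e


@njit(cache=True)
def _ww_total(waters, box, cutoff2, q_o, q_h, eps_o, sig_o, kc):
    e = 0.0
    n = waters.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            e += _ww_pair(waters[i], waters[j], box, cutoff2, q_o, q_h, eps_o, sig_o, kc)
    return e


@njit(cache=True)
def _sw_energy_water(
    w, spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
):
    """(electrostatic, vdW) energy of one water with the whole solute.

    Per-site-pair minimum image.  The LJ term uses a soft-core coupling in lam_v:
    at lam_v = 1 it reduces exactly to plain Lennard-Jones; as lam_v -> 0 with
    alpha > 0 the repulsive core is smoothly removed.  Charges scale linearly
    with lam_e.
    """
    elec = 0.0
    vdw = 0.0
    for k in range(spos.shape[0]):
        eps_ij = math.sqrt(seps[k] * eps_o)
        sig_ij = 0.5 * (ssig[k] + sig_o)
        for a in range(3):
            qa = q_o if a == 0 else q_h
            dx = _mic(w[a, 0] - spos[k, 0], box)
            dy = _mic(w[a, 1] - spos[k, 1], box)
            dz = _mic(w[a, 2] - spos[k, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            elec += kc * lam_e * sq[k] * qa / r
            if a == 0 and eps_ij > 0.0:
                s6 = (r2 / (sig_ij * sig_ij)) ** 3
                denom = alpha * (1.0 - lam_v) + s6
                vdw += 4.0 * eps_ij * lam_v * (1.0 / (denom * denom) - 1.0 / denom)
    return elec, vdw


@njit(cache=True)
def _sw_total(waters, spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha):
    elec = 0.0
    vdw = 0.0
    for i in range(waters.shape[0]):
        e, v = _sw_energy_water(
            waters[i], spos, sq, seps, ssig, box, q_o, q_h, eps_o, sig_o, kc, lam_e, lam_v, alpha
        )
        elec += e
        vdw += v
    return elec, vdw


# ---------------------------------------------------------------------------
# Structure-level energies
# ---------------------------------------------------------------------------


def interaction_energy(
    group_a: Structure,
    group_b: Structure,
    box_edge: float,
    ff: ForceFieldTable,
    cutoff: Optional[float] = None,
) -> tuple[float, float, float]:
    """Total, electrostatic and vdW interaction energy between two rigid bodies.

    Each body is treated as one molecule: the minimum-image shift is computed from
    the centre-centre (mean-position) displacement and applied to the whole of
    ``group_b``, so molecules are never split across the boundary.  If the centre
    separation exceeds the cutoff the pair contributes nothing; pass
    ``cutoff=np.inf`` to disable.  Default cutoff is the registry's.
    """
    if cutoff is None:
        cutoff = ff.cutoff
    if np.isfinite(cutoff) and box_edge < 2.0 * cutoff:
        raise ValueError("box must be at least twice the cutoff")
    pa, qa_, ea, sa = ff.solute_arrays(group_a)
    pb, qb_, eb, sb = ff.solute_arrays(group_b)
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    delta = cb - ca
    shift = (delta - box_edge * np.round(delta / box_edge)) - delta
    if np.linalg.norm(delta + shift) > cutoff:
        return 0.0, 0.0, 0.0
    pb = pb + shift
    diff = pa[:, None, :] - pb[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    if np.any(r <= 0):
        raise ValueError("coincident sites between the two bodies")
    elec = ff.coulomb_constant * (qa_[:, None] * qb_[None, :] / r).sum()
    eps = np.sqrt(ea[:, None] * eb[None, :])
    sig = 0.5 * (sa[:, None] + sb[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    vdw = (4.0 * eps * (sr6**2 - sr6)).sum()
    return float(elec + vdw), float(elec), float(vdw)


def water_structure(coords: np.ndarray, ff: ForceFieldTable) -> Structure:
    """Wrap one (3, 3) water-site array as a Structure (O, H1, H2)."""
    from .structgen import Atom

    wm = ff.water
    return Structure(
        atoms=[
            Atom("O", coords[0], wm.q_o, "O(W)"),
            Atom("H", coords[1], wm.q_h, "H(W)"),
            Atom("H", coords[2], wm.q_h, "H(W)"),
        ],
        name="water",
    )


def total_energy(
    state: SimulationState,
    ff: ForceFieldTable,
    lam_elec: float = 1.0,
    lam_vdw: float = 1.0,
    softcore_alpha: float = 0.0,
) -> EnergyBreakdown:
    """Full potential energy of a solvated state with its decomposition.

    Water-water pairs honour the molecule-centre cutoff; the solute-water term is
    summed over all waters (no cutoff) with optional lambda-coupling used by the
    free-energy-perturbation layer.  A pure-water state has zero solute terms.
    """
    wm = ff.water
    waters = np.ascontiguousarray(state.waters)
    ww = 0.0
    if state.n_water > 1:
        ww = _ww_total(
            waters, state.box_edge, ff.cutoff**2, wm.q_o, wm.q_h, wm.epsilon_o, wm.sigma_o,
            ff.coulomb_constant,
        )
    elec = vdw = 0.0
    if state.solute is not None and state.n_water > 0:
        spos, sq, seps, ssig = ff.solute_arrays(state.solute)
        elec, vdw = _sw_total(
            waters, spos, sq, seps, ssig, state.box_edge,
            wm.q_o, wm.q_h, wm.epsilon_o, wm.sigma_o, ff.coulomb_constant,
            lam_elec, lam_vdw, softcore_alpha,
        )
    return EnergyBreakdown(
        total=float(ww + elec + vdw),
        solute_water=float(elec + vdw),
        water_water=float(ww),
        electrostatic_in_soln=float(elec),
        vdw_in_soln=float(vdw),
    )
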