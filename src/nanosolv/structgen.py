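"""Synthetic structure generation: BN nanotube, drug fixture, complexes, water boxes.

Everything downstream (energetics, Monte Carlo, free-energy perturbation) operates on
structures built here, so the whole pipeline is testable without any deposited
coordinates.  The tube builder produces an ideal cylindrical boron-nitride lattice
with exact bond lengths; the drug fixture is an idealized-geometry sulfasalazine
(SSZ) with published Mulliken charges on the tabulated sites; ``solvate`` fills a
cubic box with rigid three-site waters at a requested mass density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Structure",
    "BoxSpec",
    "SimulationState",
    "build_bnnt",
    "assign_bnnt_charges",
    "build_ssz_fixture",
    "place_complex",
    "solvate",
    "WATER_OH",
    "WATER_ANGLE_DEG",
    "WATER_NUMBER_DENSITY_FACTOR",
]

# Rigid three-site water geometry (O-H bond, H-O-H angle).
WATER_OH = 0.9572  # Angstrom
WATER_ANGLE_DEG = 104.52

_WATER_MOLAR_MASS = 18.0153  # g/mol
_AVOGADRO = 6.02214076e23
# molecules per Angstrom^3 at 1 g/cm^3
WATER_NUMBER_DENSITY_FACTOR = _AVOGADRO / _WATER_MOLAR_MASS / 1.0e24

# Capping bond lengths for dangling rim atoms.
_BH_BOND = 1.19
_NH_BOND = 1.01


@dataclass
class Atom:
    """One interaction site: element, Cartesian position (A), partial charge (e),
    and the Lennard-Jones site label resolved against the force-field registry."""

    element: str
    position: np.ndarray
    charge: float = 0.0
    lj_label: str = ""
    role: str = ""  # chemically meaningful tag ("O1", "S", rim...), used for placement

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")


@dataclass
class Structure:
    """An ordered collection of atoms forming one rigid body."""

    atoms: list[Atom]
    name: str = ""
    axis: Optional[np.ndarray] = None  # unit vector, set for tubes
    rigid: bool = True

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def lj_labels(self) -> list[str]:
        return [a.lj_label for a in self.atoms]

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.n_atoms, 3):
            raise ValueError("position array shape mismatch")
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    def translated(self, shift: Sequence[float]) -> "Structure":
        out = self.copy()
        out.set_positions(self.positions + np.asarray(shift, dtype=float))
        return out

    def copy(self) -> "Structure":
        return Structure(
            atoms=[Atom(a.element, a.position.copy(), a.charge, a.lj_label, a.role) for a in self.atoms],
            name=self.name,
            axis=None if self.axis is None else np.array(self.axis, dtype=float),
            rigid=self.rigid,
        )

    def validate(self, expected_total_charge: float = 0.0) -> None:
        """Enforce structure invariants: declared net charge and no overlapping atoms."""
        if abs(self.total_charge - expected_total_charge) > 1e-6:
            raise ValueError(
                f"net charge {self.total_charge:.8f} deviates from declared "
                f"{expected_total_charge}"
            )
        pos = self.positions
        if len(pos) > 1:
            d = cdist(pos, pos)
            np.fill_diagonal(d, np.inf)
            dmin = float(d.min())
            if dmin < 0.5:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(f"atoms {i} and {j} overlap at {dmin:.3f} A")


@dataclass
class BoxSpec:
    """Cubic simulation cell: edge (A), water mass density (g/cm^3), temperature (K)."""

    edge: float = 50.0
    density: float = 0.993
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.edge <= 0 or self.density <= 0 or self.temperature <= 0:
            raise ValueError("box edge, density and temperature must be positive")

    @property
    def volume(self) -> float:
        return self.edge**3

    def target_n_water(self) -> int:
        return int(round(self.density * WATER_NUMBER_DENSITY_FACTOR * self.volume))


@dataclass
class SimulationState:
    """Mutable configuration for the Monte Carlo engine: a fixed solute plus rigid
    waters in a cubic periodic box.  Water sites are stored as an (N, 3, 3) array in
    the order O, H1, H2."""

    solute: Optional[Structure]
    waters: np.ndarray  # (N, 3, 3)
    box_edge: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.waters = np.asarray(self.waters, dtype=float)
        if self.waters.size and self.waters.shape[1:] != (3, 3):
            raise ValueError("waters must have shape (N, 3, 3)")

    @property
    def n_water(self) -> int:
        return len(self.waters)

    @property
    def total_charge(self) -> float:
        # each rigid water is neutral by construction
        return 0.0 if self.solute is None else self.solute.total_charge

    def copy(self) -> "SimulationState":
        return SimulationState(
            solute=None if self.solute is None else self.solute.copy(),
            waters=self.waters.copy(),
            box_edge=self.box_edge,
            temperature=self.temperature,
        )


# ---------------------------------------------------------------------------
# Boron-nitride nanotube
# ---------------------------------------------------------------------------


def build_bnnt(
    n: int = 9,
    rows: int = 22,
    bond_length: float = 1.45,
    cap: bool = True,
    charge_b: float = 0.83,
    charge_n: float = -0.83,
) -> Structure:
    """Build a zigzag (n, 0) boron-nitride nanotube as an ideal cylindrical lattice.

    The honeycomb sheet is rolled so that every B-N nearest-neighbour distance equals
    ``bond_length`` exactly: the circumferential component of the diagonal bonds is a
    chord of the cylinder, and the axial row spacing is adjusted to compensate.
    ``rows`` counts the rings of ``n`` atoms along the axis; alternating rows carry B
    and N, so ``rows=22`` with ``n=9`` gives the 99 B + 99 N (198 atom) tube.  With
    ``cap`` set, each rim atom is saturated with one hydrogen along its severed bond
    direction (B-H 1.19 A, N-H 1.01 A).  The tube axis is +z through the origin, and
    the tube is centred at z = 0.
    """
    if n < 3:
        raise ValueError("chirality index n must be >= 3")
    if not (1.3 <= bond_length <= 1.6):
        raise ValueError("bond_length outside the plausible 1.3-1.6 A window")
    if rows < 2:
        raise ValueError("need at least 2 rows for one full B-N ring pair")
    d = bond_length
    radius = math.sqrt(3.0) * d * n / (2.0 * math.pi)
    # chord spanned by the diagonal bond (angular step pi/n around the cylinder)
    chord = 2.0 * radius * math.sin(math.pi / (2.0 * n))
    dz_diag = math.sqrt(max(d * d - chord * chord, 0.0))
    # z offsets within one 4-row period and the period length
    offsets = [0.0, dz_diag, dz_diag + d, 2.0 * dz_diag + d]
    period = 2.0 * dz_diag + 2.0 * d

    atoms: list[Atom] = []
    zs = []
    for r in range(rows):
        g, m = divmod(r, 4)
        z = g * period + offsets[m]
        zs.append(z)
        half_shift = 0.5 if m in (1, 2) else 0.0  # columns offset by half a step
        element = "B" if r % 2 == 0 else "N"
        for k in range(n):
            phi = 2.0 * math.pi * (k + half_shift) / n
            pos = np.array([radius * math.cos(phi), radius * math.sin(phi), z])
            atoms.append(
                Atom(
                    element,
                    pos,
                    lj_label="B(NT)" if element == "B" else "N(NT)",
                    role="rim" if r in (0, rows - 1) else "wall",
                )
            )

    if cap:
        # bottom rim misses its straight-down bond, top rim its straight-up bond
        for a in list(atoms):
            if a.role != "rim":
                continue
            if abs(a.position[2] - zs[0]) < 1e-9:
                direction = np.array([0.0, 0.0, -1.0])
            elif abs(a.position[2] - zs[-1]) < 1e-9:
                direction = np.array([0.0, 0.0, 1.0])
            else:
                continue
            blen = _BH_BOND if a.element == "B" else _NH_BOND
            atoms.append(Atom("H", a.position + blen * direction, lj_label="H", role="cap"))

    tube = Structure(atoms=atoms, name=f"bnnt_{n}_0_rows{rows}", axis=np.array([0.0, 0.0, 1.0]))
    # centre along the axis
    zmid = 0.5 * (zs[0] + zs[-1])
    tube.set_positions(tube.positions - np.array([0.0, 0.0, zmid]))
    tube = assign_bnnt_charges(tube, charge_b, charge_n)
    tube.validate()
    return tube


def assign_bnnt_charges(s: Structure, qB: float, qN: float) -> Structure:
    """Assign uniform partial charges to a B/N/H tube: every B gets ``qB``, every N
    ``qN``, and the cap hydrogens absorb minus the residual in equal shares so the
    total charge is exactly zero."""
    allowed = {"B", "N", "H"}
    if not set(a.element for a in s.atoms) <= allowed:
        raise ValueError("charge scheme applies only to B/N/H nanotube structures")
    out = s.copy()
    heavies = 0.0
    n_h = 0
    for a in out.atoms:
        if a.element == "B":
            a.charge = qB
            heavies += qB
        elif a.element == "N":
            a.charge = qN
            heavies += qN
        else:
            n_h += 1
    if n_h:
        qh = -heavies / n_h
        for a in out.atoms:
            if a.element == "H":
                a.charge = qh
    elif abs(heavies) > 1e-6:
        raise ValueError("uncapped tube with unbalanced B/N charges cannot be neutralized")
    return out


# ---------------------------------------------------------------------------
# Sulfasalazine fixture
# ---------------------------------------------------------------------------


def _hexagon(center: np.ndarray, u: np.ndarray, v: np.ndarray, radius: float, start: float) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = start + k * math.pi / 3.0
        pts.append(center + radius * (math.cos(ang) * u + math.sin(ang) * v))
    return pts


def _unit(vec) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    return vec / np.linalg.norm(vec)


def build_ssz_fixture(tautomer: Literal["keto", "enol"] = "keto") -> Structure:
    """Idealized rigid sulfasalazine (C18 O5 N4 S H14, 42 atoms).

    The skeleton — salicylate ring, azo bridge, sulfonyl-phenyl ring, sulfonamide,
    pyridine — is laid out from standard bond lengths; exact internal geometry is a
    documented idealization.  Atoms corresponding to the published Mulliken-charge
    sites (C1, C2, O1-O3, N1-N4, S, O(S), H2, H3) carry the printed charge for the
    chosen tautomer; the residual charge is spread uniformly over the remaining
    hydrogens so the molecule is exactly neutral.
    """
    charges = _ssz_site_charges(tautomer)

    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    rc = 1.39  # aromatic ring circumradius = C-C bond

    atoms: list[Atom] = []

    def add(element: str, pos: np.ndarray, role: str = "") -> np.ndarray:
        atoms.append(Atom(element, np.asarray(pos, dtype=float), role=role))
        return np.asarray(pos, dtype=float)

    # --- central phenyl ring B (bears SO2 at +x, azo at -x)
    ring_b = _hexagon(np.zeros(3), ex, ey, rc, 0.0)
    for i, p in enumerate(ring_b):
        add("C", p, role=f"CB{i}")
    for i in (1, 2, 4, 5):  # ring hydrogens
        add("H", ring_b[i] + 1.08 * _unit(ring_b[i]), role="H_ring")

    # --- sulfonyl group
    s_pos = add("S", ring_b[0] + 1.76 * ex, role="S")
    add("O", s_pos + 1.43 * _unit([0.35, 0.80, 0.49]), role="O_S")
    add("O", s_pos + 1.43 * _unit([0.35, -0.80, 0.49]), role="O_S2")
    # sulfonamide N-H
    n3 = add("N", s_pos + 1.63 * _unit([0.77, 0.0, -0.64]), role="N3")
    add("H", n3 + 1.01 * _unit([0.0, 0.9, -0.44]), role="H_N")

    # --- pyridine ring (N4 in the ring), attached at n3
    upy = _unit([0.94, 0.0, -0.34])
    c2p = n3 + 1.40 * upy
    vpy = _unit(np.cross([0.0, 1.0, 0.0], upy))
    ring_p = _hexagon(c2p + rc * upy, upy, vpy, rc, math.pi)  # vertex 0 = c2p
    add("C", ring_p[0], role="CP0")
    add("N", ring_p[1], role="N4")  # ortho ring nitrogen
    for i in (2, 3, 4, 5):
        add("C", ring_p[i], role=f"CP{i}")
    for i in (2, 3, 4, 5):
        out_dir = _unit(ring_p[i] - (c2p + rc * upy))
        add("H", ring_p[i] + 1.08 * out_dir, role="H_ring")

    # --- azo bridge off ring B at -x
    b3 = ring_b[3]
    n1 = add("N", b3 + 1.41 * _unit([-0.866, 0.5, 0.0]), role="N1")
    n2 = add("N", n1 + 1.25 * _unit([-0.866, -0.5, 0.0]), role="N2")

    # --- salicylate ring A
    a0 = n2 + 1.41 * _unit([-0.866, 0.5, 0.0])
    ca = a0 + rc * _unit([-0.866, 0.5, 0.0])
    ua = _unit(a0 - ca)
    va = _unit(np.cross([0.0, 0.0, 1.0], ua))
    ring_a = _hexagon(ca, ua, va, rc, 0.0)  # vertex 0 = a0
    add("C", ring_a[0], role="CA0")
    add("C", ring_a[1], role="CA1")
    c2 = add("C", ring_a[2], role="C2")  # ring carbon bearing the enol/keto oxygen
    add("C", ring_a[3], role="CA3")
    add("C", ring_a[4], role="CA4")
    add("C", ring_a[5], role="CA5")
    for i in (1, 4, 5):
        add("H", ring_a[i] + 1.08 * _unit(ring_a[i] - ca), role="H_ring")

    # carboxylic acid on A3: C1 with carbonyl O1 and hydroxyl O2-H2
    out3 = _unit(ring_a[3] - ca)
    c1 = add("C", ring_a[3] + 1.48 * out3, role="C1")
    perp = _unit(np.cross(out3, [0.0, 0.0, 1.0]))
    o1 = add("O", c1 + 1.23 * _unit(out3 + 0.9 * perp + 0.25 * np.array([0, 0, 1.0])), role="O1")
    o2 = add("O", c1 + 1.36 * _unit(out3 - 0.9 * perp - 0.25 * np.array([0, 0, 1.0])), role="O2")
    add("H", o2 + 0.97 * _unit(out3 - 0.3 * perp), role="H2")

    # enol/keto oxygen on C2 (phenol O-H in the enol form, C=O in the keto form)
    out2 = _unit(ring_a[2] - ca)
    o3 = add("O", c2 + 1.33 * out2, role="O3")
    add("H", o3 + 0.97 * _unit(out2 + 0.5 * np.array([0, 0, 1.0])), role="H3")

    # --- charges and LJ labels
    residual_h: list[Atom] = []
    total_listed = 0.0
    for a in atoms:
        if a.role in charges:
            a.charge = charges[a.role]
            total_listed += a.charge
        elif a.element == "H":
            residual_h.append(a)
        else:
            a.charge = 0.0
    if residual_h:
        q_res = -total_listed / len(residual_h)
        for a in residual_h:
            a.charge = q_res

    carbon_pos = np.array([a.position for a in atoms if a.element == "C"])
    for a in atoms:
        if a.element == "C":
            a.lj_label = "C"
        elif a.element == "S":
            a.lj_label = "S"
        elif a.element == "N":
            a.lj_label = "N"
        elif a.element == "O":
            a.lj_label = "O(W)"  # solute O absent from the registry: water-O LJ fallback
        else:  # hydrogen: distinguish H-on-carbon from heteroatom H
            dmin = np.min(np.linalg.norm(carbon_pos - a.position, axis=1))
            a.lj_label = "H on C" if dmin < 1.2 else "H"

    s = Structure(atoms=atoms, name=f"ssz_{tautomer}")
    s.validate()
    _check_formula(s, {"C": 18, "O": 5, "N": 4, "S": 1, "H": 14})
    return s


def _ssz_site_charges(tautomer: str) -> dict[str, float]:
    from .io import load_table  # local import to avoid a cycle

    tab = load_table("table3_charges")
    key = f"SSZ_{tautomer}"
    row = tab[tab["species"] == key]
    if row.empty:
        raise ValueError(f"unknown tautomer {tautomer!r}; expected 'keto' or 'enol'")
    row = row.iloc[0]
    return {c if c != "O_S" else "O_S": float(row[c]) for c in tab.columns if c != "species"}


def _check_formula(s: Structure, formula: dict[str, int]) -> None:
    counts: dict[str, int] = {}
    for a in s.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
    if counts != formula:
        raise AssertionError(f"formula mismatch: {counts} != {formula}")


# ---------------------------------------------------------------------------
# Complex placement
# ---------------------------------------------------------------------------

_SITE_CONTACT_ROLE = {
    "carbonyl_v1": "O1",
    "carbonyl_v2": "O1",
    "sulfonamide": "O_S",
    "pyridine": "N4",
}


def place_complex(
    tube: Structure,
    drug: Structure,
    site: str = "carbonyl_v2",
    gap: float = 2.55,
) -> Structure:
    """Deterministically pose the drug against the tube outer wall.

    The named interaction atom (carbonyl O, sulfonyl O or pyridine N) is placed over
    a boron atom near the tube's axial midplane, on the radially outward direction,
    and the drug body is rotated to point away from the tube.  The pose is then slid
    along the outward normal until the *minimum* cross-body distance equals ``gap``
    — so the contact pair sits at the requested closest approach.  No randomness is
    involved: identical inputs give an identical pose.
    """
    if tube.axis is None:
        raise ValueError("tube structure must carry an axis")
    if not (2.0 <= gap <= 5.0):
        raise ValueError("gap must lie in [2, 5] A")
    if site not in _SITE_CONTACT_ROLE:
        raise ValueError(f"unknown site {site!r}")

    tube_pos = tube.positions
    # pick the boron atom closest to the axial midplane (deterministic tie-break on
    # index order), biased to phi=0 by choosing max x among candidates
    b_idx = [i for i, a in enumerate(tube.atoms) if a.element == "B"]
    z = tube_pos[b_idx, 2]
    near = [i for i, zz in zip(b_idx, z) if abs(zz) <= np.min(np.abs(z)) + 1e-9]
    anchor = max(near, key=lambda i: tube_pos[i, 0])
    anchor_pos = tube_pos[anchor]
    outward = anchor_pos - np.array([0.0, 0.0, anchor_pos[2]])
    outward = _unit(outward)

    roles = [a.role for a in drug.atoms]
    contact_role = _SITE_CONTACT_ROLE[site]
    contact = roles.index(contact_role)

    body = drug.copy()
    pos = body.positions
    # orient the interaction bond at the wall: the director atom (the heavy atom
    # behind the contact site) is placed on the outward normal behind the contact,
    # so the named atom is the body's closest point to the tube
    if site == "pyridine":
        ring = [i for i, r in enumerate(roles) if r in ("CP0", "N4", "CP2", "CP3", "CP4", "CP5")]
        director_pos = pos[ring].mean(axis=0)
    else:
        director_pos = pos[roles.index({"carbonyl_v1": "C1", "carbonyl_v2": "C1", "sulfonamide": "S"}[site])]
    vbond = _unit(pos[contact] - director_pos)  # points from body toward the tube
    rot, _ = Rotation.align_vectors(-outward[None, :], vbond[None, :])
    pos = rot.apply(pos - pos[contact])
    if site == "carbonyl_v1":
        # second vertical approach: roll the body a quarter turn about the normal
        pos = Rotation.from_rotvec(0.5 * math.pi * outward).apply(pos)
    pos = pos + anchor_pos + gap * outward

    # slide along the outward normal until min cross-body distance == gap
    for _ in range(60):
        d = cdist(tube_pos, pos)
        dmin = float(d.min())
        if abs(dmin - gap) < 1e-4:
            break
        pos = pos + (gap - dmin) * outward
    d = cdist(tube_pos, pos)
    if float(d.min()) < 2.0 - 1e-9:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"steric clash: tube atom {i} and drug atom {j} at {float(d.min()):.2f} A"
        )
    body.set_positions(pos)

    merged = Structure(
        atoms=tube.copy().atoms + body.atoms,
        name=f"{tube.name}+{drug.name}@{site}",
        axis=None if tube.axis is None else np.array(tube.axis, dtype=float),
    )
    merged.validate(expected_total_charge=tube.total_charge + drug.total_charge)
    return merged


# ---------------------------------------------------------------------------
# Solvation
# ---------------------------------------------------------------------------


def _water_template() -> np.ndarray:
    """Site offsets (O, H1, H2) for one rigid water, O at the origin."""
    half = math.radians(WATER_ANGLE_DEG / 2.0)
    h1 = WATER_OH * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = WATER_OH * np.array([-math.sin(half), 0.0, math.cos(half)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def solvate(
    solute: Optional[Structure],
    box: BoxSpec,
    seed: int,
    carve_distance: float = 2.6,
) -> SimulationState:
    """Fill a cubic box with rigid waters at the requested density.

    Waters are seeded on a uniform cubic lattice with a small random jitter and
    random orientations, then any water whose oxygen lies within ``carve_distance``
    of a solute atom is removed.  The solute (if any) is centred in the box.  The
    construction is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_target = box.target_n_water()
    if n_target < 1:
        raise ValueError("box too small to hold a single water")

    center = np.full(3, box.edge / 2.0)
    sol = None
    sol_pos = None
    if solute is not None:
        sol = solute.copy()
        sol.set_positions(sol.positions - sol.centroid() + center)
        sol_pos = sol.positions
        extent = float(np.max(np.linalg.norm(solute.positions - solute.centroid(), axis=1)))
        if box.edge < 2.0 * (extent + 3.0):
            raise ValueError(
                f"box edge {box.edge} too small for solute extent {extent:.1f} A"
            )

    m = int(math.ceil(n_target ** (1.0 / 3.0)))
    spacing = box.edge / m
    jitter = min(0.15, 0.1 * spacing)
    grid = (np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), axis=-1).reshape(-1, 3) + 0.5) * spacing
    keep = rng.permutation(len(grid))[:n_target]
    o_pos = grid[keep] + rng.uniform(-jitter, jitter, size=(n_target, 3))

    template = _water_template()
    rots = Rotation.random(n_target, rng=rng).as_matrix()
    waters = o_pos[:, None, :] + np.einsum("nij,kj->nki", rots, template)

    if sol_pos is not None:
        d = cdist(waters[:, 0, :], sol_pos)
        waters = waters[d.min(axis=1) >= carve_distance]

    return SimulationState(
        solute=sol, waters=waters, box_edge=box.edge, temperature=box.temperature
    )
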