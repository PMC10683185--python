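"""File formats, configuration, and run provenance.

Structures travel as XYZ (element x y z, A) or PDB (HETATM records with a CRYST1
box); partial charges and LJ labels, which neither format carries, live in a
sidecar CSV (atom_index, element, charge, lj_label) honoured on read when present.
Run configuration is YAML with strict validation; a RunManifest records the seed,
config hash and file paths so any output can be regenerated bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pydantic
import yaml

from .structgen import Atom, Structure

__all__ = [
    "HARTREE_TO_KCAL",
    "load_table",
    "read_structure",
    "write_structure",
    "RunConfig",
    "load_config",
    "RunManifest",
]

HARTREE_TO_KCAL = 627.5095


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged transcription tables by stem (e.g. 'table5_aim')."""
    path = resources.files("nanosolv.tables").joinpath(f"{name}.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".charges.csv")


def write_structure(
    s: Structure,
    path: str | Path,
    fmt: Optional[str] = None,
    box_edge: Optional[float] = None,
    sidecar: bool = True,
) -> None:
    """Write a structure as XYZ or PDB (format inferred from the suffix when not
    given), plus a sidecar charge/LJ-label CSV."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        lines = [str(s.n_atoms), s.name]
        for a in s.atoms:
            x, y, z = a.position
            lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        lines = []
        if box_edge is not None:
            lines.append(
                f"CRYST1{box_edge:9.3f}{box_edge:9.3f}{box_edge:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
            )
        for i, a in enumerate(s.atoms, start=1):
            x, y, z = a.position
            lines.append(
                f"HETATM{i % 100000:5d} {a.element:<4.4s}MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2.2s}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    if sidecar:
        pd.DataFrame(
            {
                "atom_index": np.arange(s.n_atoms),
                "element": s.elements,
                "charge": s.charges,
                "lj_label": s.lj_labels,
            }
        ).to_csv(_sidecar_path(path), index=False)


def read_structure(path: str | Path, fmt: Optional[str] = None) -> Structure:
    """Read XYZ or PDB back into a Structure; malformed records are reported with
    their line number.  A sidecar charge CSV next to the file is honoured."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    atoms: list[Atom] = []
    text = path.read_text().splitlines()
    if fmt == "xyz":
        if len(text) < 2:
            raise ValueError(f"{path}: truncated XYZ header")
        try:
            n = int(text[0].split()[0])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:1: bad atom count {text[0]!r}") from None
        name = text[1].strip()
        for ln, line in enumerate(text[2 : 2 + n], start=3):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 'element x y z', got {line!r}")
            try:
                pos = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ValueError(f"{path}:{ln}: bad coordinate token in {line!r}") from None
            atoms.append(Atom(parts[0], np.array(pos)))
        if len(atoms) != n:
            raise ValueError(f"{path}: header declares {n} atoms, found {len(atoms)}")
    elif fmt == "pdb":
        name = path.stem
        for ln, line in enumerate(text, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                pos = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise ValueError(f"{path}:{ln}: bad coordinate field in {line!r}") from None
            element = line[76:78].strip() or line[12:16].strip()[:1]
            atoms.append(Atom(element, np.array(pos)))
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")

    s = Structure(atoms=atoms, name=name)
    side = _sidecar_path(path)
    if side.exists():
        tab = pd.read_csv(side)
        if len(tab) != s.n_atoms:
            raise ValueError(f"{side}: sidecar row count {len(tab)} != atom count {s.n_atoms}")
        for a, rec in zip(s.atoms, tab.itertuples()):
            a.charge = float(rec.charge)
            a.lj_label = str(rec.lj_label)
    return s


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(pydantic.BaseModel):
    """Validated simulation configuration with the published protocol as defaults.
    A seed is mandatory: reproducibility is part of the contract."""

    model_config = pydantic.ConfigDict(extra="forbid")

    edge: float = 50.0  # A
    density: float = 0.993  # g/cm^3
    temperature: float = 298.0  # K
    d_translate: float = 0.13  # A
    d_rotate: float = 10.0  # degrees
    cutoff: float = 9.5  # A
    n_equil: int = 0
    n_prod: int = 0
    sample_every: int = 100
    coord_every: int = 0
    seed: int

    @pydantic.field_validator("edge", "density", "temperature", "cutoff")
    @classmethod
    def _positive(cls, v: float, info: pydantic.ValidationInfo) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @pydantic.field_validator("n_equil", "n_prod")
    @classmethod
    def _non_negative(cls, v: int, info: pydantic.ValidationInfo) -> int:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration; every schema violation is
    reported at once (pydantic collects them)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one run: stable hash of the resolved config, seed, package
    version, and the files read/written."""

    config: dict
    seed: int
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self) -> str:
        from . import __version__

        return json.dumps(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": __version__,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "created": self.created,
            },
            indent=2,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
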