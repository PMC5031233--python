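"""Readers and writers for geometries, Hessians, multipole tables and
training tables.

On-disk conventions
-------------------
* geometries: standard (multi-frame) XYZ, coordinates in angstrom;
* Hessians: whitespace-separated plain text, either the full 3N x 3N matrix
  or its lower triangle in row-major order, in hartree/bohr^2;
* multipole tables: CSV with header ``atom,element,frame,Q00,...,Q44s``,
  moments in atomic units (e bohr^l), 25 real spherical-tensor components
  per atom in canonical order (Q00; Q10, Q11c, Q11s; ... Q44s);
* training tables: CSV ``atom,feature_1..feature_d,Q00..Q44s``.

Internally all quantities are stored in atomic units (bohr, hartree,
electron masses); conversion happens here and only here.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from ._tensor_tables import COMPONENT_NAMES

__all__ = [
    "LabeledGeometry",
    "HessianMatrix",
    "MultipoleSet",
    "TrainingTable",
    "ParseError",
    "read_xyz",
    "write_xyz",
    "read_hessian",
    "write_hessian",
    "read_multipoles",
    "write_multipoles",
    "read_training_table",
    "write_training_table",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclasses.dataclass
class LabeledGeometry:
    """A molecular conformation: element labels, coordinates and masses.

    Coordinates are stored in bohr, masses in electron masses.  I/O is in
    angstrom / amu.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3), bohr
    masses: np.ndarray  # (N,), electron masses
    comment: str = ""

    def __post_init__(self):
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) < 2:
            raise ValueError("a geometry needs at least 2 atoms")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.masses is None:
            self.masses = np.array(
                [constants.atomic_mass_me(e) for e in self.elements]
            )
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.elements),):
            raise ValueError("masses shape does not match atom count")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        for e in self.elements:
            constants.atomic_number(e)  # raises for unknown symbols

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def with_coords(self, coords: np.ndarray, comment: str | None = None) -> "LabeledGeometry":
        return LabeledGeometry(
            self.elements, coords, self.masses,
            self.comment if comment is None else comment,
        )


@dataclasses.dataclass
class HessianMatrix:
    """Cartesian second-derivative matrix in hartree/bohr^2, symmetrized."""

    values: np.ndarray
    atom_count: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n3 = 3 * self.atom_count
        if self.values.shape != (n3, n3):
            raise ValueError(f"Hessian must be {n3}x{n3}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Hessian contains non-finite entries")
        scale = np.abs(self.values).max() or 1.0
        asym = np.abs(self.values - self.values.T).max()
        if asym > 1e-10 * scale:
            raise ValueError(
                f"Hessian asymmetric beyond tolerance: {asym / scale:.3e} relative"
            )
        self.values = 0.5 * (self.values + self.values.T)


@dataclasses.dataclass
class MultipoleSet:
    """Per-atom real spherical-tensor moments Q_lm, l <= 4 (25 components).

    ``frame`` is "ALF" (each atom's moments expressed in its own atomic
    local frame) or "global".
    """

    values: np.ndarray  # (N, 25), atomic units
    frame: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 25:
            raise ValueError("multipole table must have exactly 25 components per atom")
        if self.frame not in ("ALF", "global"):
            raise ValueError(f"unknown frame tag: {self.frame!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite multipole components")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class TrainingTable:
    """Per-atom kriging training data: features and the 25 moment outputs."""

    atom: int
    features: np.ndarray  # (n, 3N-6)
    outputs: np.ndarray   # (n, 25)
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.features.shape[0] != self.outputs.shape[0]:
            raise ValueError("feature and output row counts differ")
        if self.outputs.shape[1] != 25:
            raise ValueError("outputs must have 25 columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path) -> list[LabeledGeometry]:
    """Read a (multi-frame) XYZ file; coordinates angstrom -> bohr.

    Masses are filled from the built-in standard-atomic-weight table.
    """
    lines = Path(path).read_text().splitlines()
    geometries = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 1 >= len(lines):
            raise ParseError(f"{path}: line {i + 1}: missing comment line")
        comment = lines[i + 1]
        elements, coords = [], []
        for k in range(count):
            j = i + 2 + k
            if j >= len(lines):
                raise ParseError(
                    f"{path}: line {j + 1}: expected {count} atom lines, "
                    f"found {k}"
                )
            parts = lines[j].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {j + 1}: expected 'element x y z', got {lines[j]!r}"
                )
            elements.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ParseError(
                    f"{path}: line {j + 1}: non-numeric coordinate"
                ) from None
        coords = np.array(coords) * constants.BOHR_PER_ANGSTROM
        masses = np.array([constants.atomic_mass_me(e) for e in elements])
        geometries.append(LabeledGeometry(elements, coords, masses, comment))
        i += 2 + count
    if not geometries:
        raise ParseError(f"{path}: no frames found")
    return geometries


def write_xyz(geometries: Sequence[LabeledGeometry], path) -> None:
    """Write geometries as multi-frame XYZ in angstrom."""
    geometries = list(geometries)
    if not geometries:
        raise ValueError("cannot write an empty sequence of geometries")
    with open(path, "w") as fh:
        for idx, g in enumerate(geometries):
            comment = g.comment or f"frame {idx}"
            fh.write(f"{g.n_atoms}\n{comment}\n")
            ang = g.coords * constants.ANGSTROM_PER_BOHR
            for e, (cx, cy, cz) in zip(g.elements, ang):
                fh.write(f"{e:<3s} {cx:20.12f} {cy:20.12f} {cz:20.12f}\n")


# ---------------------------------------------------------------------------
# Hessian

def read_hessian(path, n_atoms: int) -> HessianMatrix:
    """Read a plain-text Hessian, full 3Nx3N or lower-triangle row-major."""
    values = np.array(Path(path).read_text().split(), dtype=float)
    n3 = 3 * n_atoms
    full, tri = n3 * n3, n3 * (n3 + 1) // 2
    if values.size == full:
        h = values.reshape(n3, n3)
    elif values.size == tri:
        h = np.zeros((n3, n3))
        rows, cols = np.tril_indices(n3)
        h[rows, cols] = values
        h = h + np.tril(h, -1).T
    else:
        raise ParseError(
            f"{path}: found {values.size} numbers; expected {full} "
            f"(full 3Nx3N) or {tri} (lower triangle) for N={n_atoms}"
        )
    return HessianMatrix(0.5 * (h + h.T), n_atoms)


def write_hessian(hessian: HessianMatrix, path) -> None:
    np.savetxt(path, hessian.values, fmt="%24.16e")


# ---------------------------------------------------------------------------
# Multipole tables

_MP_COLUMNS = ["atom", "element", "frame"] + COMPONENT_NAMES


def read_multipoles(path) -> MultipoleSet:
    """Read a per-atom multipole CSV (25 named moment columns)."""
    df = pd.read_csv(path)
    missing = [c for c in _MP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing columns {missing}; higher-rank moments are "
            "never implicitly zero-filled"
        )
    extra = [c for c in df.columns if c not in _MP_COLUMNS]
    if extra:
        raise ParseError(f"{path}: unexpected columns {extra}")
    frames = set(df["frame"])
    if len(frames) != 1:
        raise ParseError(f"{path}: mixed frame tags {sorted(frames)}")
    frame = frames.pop()
    df = df.sort_values("atom")
    return MultipoleSet(df[COMPONENT_NAMES].to_numpy(float), frame=str(frame))


def write_multipoles(moments: MultipoleSet, elements: Sequence[str], path) -> None:
    df = pd.DataFrame(moments.values, columns=COMPONENT_NAMES)
    df.insert(0, "frame", moments.frame)
    df.insert(0, "element", list(elements))
    df.insert(0, "atom", np.arange(moments.n_atoms))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Training tables

def write_training_table(table: TrainingTable, path) -> None:
    d = table.n_features
    cols = [f"feature_{i + 1}" for i in range(d)] + COMPONENT_NAMES
    df = pd.DataFrame(np.hstack([table.features, table.outputs]), columns=cols)
    df.insert(0, "atom", table.atom)
    df.to_csv(path, index=False)


def read_training_table(path) -> TrainingTable:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("feature_")]
    if not feat_cols or any(c not in df.columns for c in COMPONENT_NAMES):
        raise ParseError(f"{path}: not a training table (feature_*/Q* columns missing)")
    atoms = set(df["atom"])
    if len(atoms) != 1:
        raise ParseError(f"{path}: a training table holds one atom, found {sorted(atoms)}")
    return TrainingTable(
        atom=int(atoms.pop()),
        features=df[feat_cols].to_numpy(float),
        outputs=df[COMPONENT_NAMES].to_numpy(float),
    )
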