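"""Atomic local frames (ALF) and rotation-invariant conformational features.

Every atom gets a right-handed local frame anchored on itself (origin), its
heaviest bonded neighbour (x-axis) and the next heaviest (xy-plane); ties
are broken by a recursive Cahn-Ingold-Prelog-like comparison of neighbour
shells and finally by lowest atom index.  For terminal atoms (one bond) the
xy-plane atom is taken from the heaviest neighbour-of-neighbour.

The 3N-6 features of an atom are: the two ALF distances and the suspended
angle, followed by spherical coordinates (r, theta, phi) of every non-ALF
atom in ascending input-index order, all expressed in the ALF.  They are
invariant under global rotation and translation of the molecule.

The bond graph is detected from covalent radii on the seed geometry and is
meant to be computed once and reused for a whole sampled ensemble, so the
feature layout cannot flicker between conformers.
"""
from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from . import constants
from .chem_io import LabeledGeometry, MultipoleSet
from .solid_harmonics import rotation_operator

__all__ = [
    "ALFDefinition",
    "DegenerateFrameError",
    "build_bond_graph",
    "assign_alf",
    "features",
    "feature_matrix",
    "alf_rotation",
    "rotate_multipoles",
    "rotate_multipole_set",
]

BOND_TOLERANCE = 1.2  # bonded if d <= 1.2 * (r_cov_a + r_cov_b)


class DegenerateFrameError(ValueError):
    """The three ALF atoms are (near-)collinear: no frame can be built."""


@dataclasses.dataclass
class ALFDefinition:
    """Per-atom frame anchors: (origin, x_axis atom, xy_plane atom)."""

    x_axis: tuple[int, ...]
    xy_plane: tuple[int, ...]

    def __post_init__(self):
        for i, (a, b) in enumerate(zip(self.x_axis, self.xy_plane)):
            if len({i, a, b}) != 3:
                raise ValueError(f"ALF of atom {i} must use three distinct atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.x_axis)


def build_bond_graph(geom: LabeledGeometry) -> nx.Graph:
    """Covalent bond graph: edge iff d(a,b) <= 1.2 (r_cov_a + r_cov_b)."""
    n = geom.n_atoms
    g = nx.Graph()
    g.add_nodes_from(range(n))
    radii = np.array([constants.covalent_radius_bohr(e) for e in geom.elements])
    d = np.linalg.norm(geom.coords[:, None, :] - geom.coords[None, :, :], axis=-1)
    cut = BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    ii, jj = np.where(np.triu(d <= cut, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"bond graph is disconnected: components {comps}")
    return g


def _cip_key(graph: nx.Graph, z: np.ndarray, atom: int, exclude: int, depth: int = 4):
    """Recursive neighbour-weight key for CIP-like tie-breaking."""
    if depth == 0:
        return (int(z[atom]),)
    subkeys = sorted(
        (_cip_key(graph, z, nb, atom, depth - 1) for nb in graph[atom] if nb != exclude),
        reverse=True,
    )
    return (int(z[atom]), tuple(subkeys))


def _ranked_neighbours(graph: nx.Graph, z: np.ndarray, origin: int) -> list[int]:
    """Neighbours of origin, heaviest first (CIP-like, then lowest index)."""
    return sorted(
        graph[origin],
        key=lambda nb: (_cip_key(graph, z, nb, origin), -nb),
        reverse=True,
    )


def assign_alf(graph: nx.Graph, elements) -> ALFDefinition:
    """Assign x-axis and xy-plane atoms for every atom.

    x-axis: heaviest bonded neighbour.  xy-plane: next heaviest bonded
    neighbour, or -- for terminal atoms -- the heaviest neighbour of the
    x-axis atom other than the origin.
    """
    n = len(elements)
    if n < 3:
        raise ValueError("an ALF needs at least 3 atoms")
    z = np.array([constants.atomic_number(e) for e in elements])
    x_axis, xy_plane = [], []
    for origin in range(n):
        ranked = _ranked_neighbours(graph, z, origin)
        if not ranked:
            raise ValueError(f"atom {origin} has no bonds")
        xa = ranked[0]
        if len(ranked) > 1:
            plane = ranked[1]
        else:
            second = [nb for nb in _ranked_neighbours(graph, z, xa) if nb != origin]
            if not second:
                raise ValueError(
                    f"atom {origin}: no third atom reachable for the xy-plane"
                )
            plane = second[0]
        x_axis.append(xa)
        xy_plane.append(plane)
    return ALFDefinition(tuple(x_axis), tuple(xy_plane))


def _frame_axes(geom: LabeledGeometry, alf: ALFDefinition, atom: int) -> np.ndarray:
    """Rows are the ALF axes (x, y, z) expressed in global coordinates."""
    o = geom.coords[atom]
    vx = geom.coords[alf.x_axis[atom]] - o
    vp = geom.coords[alf.xy_plane[atom]] - o
    nx_ = np.linalg.norm(vx)
    np_ = np.linalg.norm(vp)
    if nx_ == 0 or np_ == 0:
        raise DegenerateFrameError(f"coincident ALF atoms for atom {atom}")
    ex = vx / nx_
    cosang = np.clip(ex @ (vp / np_), -1.0, 1.0)
    if min(np.arccos(cosang), np.pi - np.arccos(cosang)) < 1e-6:
        raise DegenerateFrameError(
            f"ALF atoms of atom {atom} are collinear (angle within 1e-6 of 0/pi)"
        )
    ey = vp - (vp @ ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez])


def alf_rotation(geom: LabeledGeometry, alf: ALFDefinition, atom: int) -> np.ndarray:
    """Direction-cosine matrix mapping global vectors into ALF components.

    Orthogonal with det +1; applying it to the origin->x_atom vector yields
    (+r, 0, 0).
    """
    return _frame_axes(geom, alf, atom)


def features(geom: LabeledGeometry, alf: ALFDefinition, atom: int) -> np.ndarray:
    """The 3N-6 features of one atom's kriging model (bohr / radians)."""
    axes = _frame_axes(geom, alf, atom)
    o = geom.coords[atom]
    xa, pa = alf.x_axis[atom], alf.xy_plane[atom]
    vx = geom.coords[xa] - o
    vp = geom.coords[pa] - o
    rx, rp = np.linalg.norm(vx), np.linalg.norm(vp)
    angle = np.arccos(np.clip(vx @ vp / (rx * rp), -1.0, 1.0))
    feats = [rx, rp, angle]
    for j in range(geom.n_atoms):
        if j in (atom, xa, pa):
            continue
        v = axes @ (geom.coords[j] - o)
        r = np.linalg.norm(v)
        theta = np.arccos(np.clip(v[2] / r, -1.0, 1.0))
        phi = np.arctan2(v[1], v[0])
        feats.extend([r, theta, phi])
    return np.array(feats)


def feature_matrix(
    geoms, alf: ALFDefinition, atom: int
) -> np.ndarray:
    """Stack features(geom, alf, atom) over a sequence of conformers."""
    return np.array([features(g, alf, atom) for g in geoms])


def rotate_multipoles(q: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Transform one atom's 25 moments by a 3x3 orthogonal matrix.

    With D the rank-wise operator of ``rotation`` C, the result obeys
    Q'_lm = sum_m' D[m,m'] Q_lm', which is simultaneously (a) the moments of
    the distribution actively rotated by C and (b) the components in a frame
    whose coordinates are r' = C r (so C = alf_rotation(...) converts global
    moments into ALF moments; its transpose converts back).
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 25:
        raise ValueError("expected 25 multipole components")
    return q @ rotation_operator(rotation).T


def rotate_multipole_set(
    moments: MultipoleSet, geom: LabeledGeometry, alf: ALFDefinition, to_frame: str
) -> MultipoleSet:
    """Rotate all atoms' moments between the ALF and global frames."""
    if to_frame not in ("ALF", "global"):
        raise ValueError(f"unknown frame {to_frame!r}")
    if moments.frame == to_frame:
        return moments
    out = np.empty_like(moments.values)
    for a in range(moments.n_atoms):
        c = alf_rotation(geom, alf, a)
        if to_frame == "ALF":
            out[a] = rotate_multipoles(moments.values[a], c)
        else:
            out[a] = rotate_multipoles(moments.values[a], c.T)
    return MultipoleSet(out, frame=to_frame)
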