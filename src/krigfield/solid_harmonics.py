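"""Real spherical-tensor utilities built on the generated polynomial tables.

The 25 components use Racah normalization in the canonical order
Q00; Q10, Q11c, Q11s; Q20..Q22s; Q30..Q33s; Q40..Q44s, i.e. the moments of
a point charge q at r are q * S_lm(r) with S_00 = 1, S_10 = z, S_11c = x,
S_11s = y, S_20 = (3z^2 - r^2)/2, and so on.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._tensor_tables import COMPONENT_NAMES, RANK_SLICES, T_BLOCKS, solid_harmonics

__all__ = [
    "COMPONENT_NAMES",
    "RANK_SLICES",
    "solid_harmonics",
    "point_charge_moments",
    "rank_rotation_matrices",
    "rotation_operator",
    "interaction_block",
]


def point_charge_moments(charges: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Moments (25,) of a point-charge cluster about the origin (a.u.)."""
    charges = np.asarray(charges, dtype=float)
    positions = np.asarray(positions, dtype=float)
    return charges @ solid_harmonics(positions)


# fixed generic unit vectors used to solve for the rank rotation operators
@lru_cache(maxsize=1)
def _probe_points() -> np.ndarray:
    rng = np.random.default_rng(20240117)
    pts = rng.normal(size=(40, 3))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


@lru_cache(maxsize=1)
def _probe_harmonics() -> np.ndarray:
    return solid_harmonics(_probe_points())


def rank_rotation_matrices(rotation: np.ndarray) -> list[np.ndarray]:
    """Orthogonal rank-l operators D_l with S_lm(C r) = sum_m' D_l[m,m'] S_lm'(r).

    ``rotation`` is the 3x3 orthogonal matrix C.  Solved exactly (to
    numerical precision) by least squares on fixed generic directions.
    """
    C = np.asarray(rotation, dtype=float)
    if C.shape != (3, 3) or np.abs(C @ C.T - np.eye(3)).max() > 1e-8:
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    pts = _probe_points()
    base = _probe_harmonics()
    rotated = solid_harmonics(pts @ C.T)
    out = []
    for l, sl in RANK_SLICES.items():
        A = base[:, sl]            # (K, 2l+1) values of S_lm'(r_k)
        B = rotated[:, sl]         # (K, 2l+1) values of S_lm(C r_k)
        D, *_ = np.linalg.lstsq(A, B, rcond=None)
        out.append(D.T)
    return out


def rotation_operator(rotation: np.ndarray) -> np.ndarray:
    """Block-diagonal 25x25 operator acting on a full moment vector."""
    blocks = rank_rotation_matrices(rotation)
    op = np.zeros((25, 25))
    for l, sl in RANK_SLICES.items():
        op[sl, sl] = blocks[l]
    return op


def interaction_block(l1: int, l2: int, r_ab: np.ndarray) -> np.ndarray:
    """T tensor block (2l1+1, 2l2+1) for separation vector r_ab (bohr).

    E(pair) = sum Q^A_{l1 m1} T_{m1 m2} Q^B_{l2 m2} with r_ab = r_B - r_A.
    Only l1 + l2 <= 4 is tabulated (L = l1 + l2 + 1 <= 5 truncation).
    """
    try:
        f = T_BLOCKS[(l1, l2)]
    except KeyError:
        raise ValueError(f"rank combination ({l1},{l2}) beyond the L=5 truncation") from None
    return np.atleast_2d(np.asarray(f(*np.asarray(r_ab, dtype=float))))
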