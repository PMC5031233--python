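"""Synthetic stand-in for the ab initio / density-partitioning stage.

Real atomic multipole moments come from partitioning a quantum-chemical
electron density into atomic basins; that step needs external software and
wavefunctions.  This module replaces it with a deterministic, smooth,
conformation-dependent surrogate so the whole pipeline (sample -> features
-> train -> predict -> energy -> S-curve) runs end to end with no external
data:

* monopoles follow bond-wise charge transfer, delta_q = c_ab (1/r_ab -
  1/r0_ab) moved from atom b to atom a, so the molecular net charge is
  conserved exactly across conformers;
* dipoles couple to the bonded-neighbour directions expressed in the atom's
  own local frame, Q1(a) += gain_a * sum_b u_ab^ALF / r_ab, so the moments
  are invariant under global rigid motion;
* all higher components are constant base values (nonzero, so every rank
  contributes to the electrostatic energy);
* optional seeded Gaussian noise models integration-quadrature noise.

The map from geometry to moments is affine in smooth descriptors: rich
enough to be conformation-dependent, simple enough to be recovered nearly
exactly by kriging, which is what makes it useful for pipeline validation.

Fixtures
--------
``make_fixture`` builds small self-contained test systems.  The 16-atom
``chain16`` and ``ring16`` fixtures reproduce the covalent topologies of an
open-chain tetrose (HOCH2-CHOH-CHOH-CHO) and a tetrofuranose (one
five-membered C4O ring with three hydroxyls); their Hessians come from
analytic harmonic pair potentials whose minimum is the fixture geometry
itself, so the vibrational analysis is exact.  ``double_well`` provides
several well-separated seed minima of the same triatomic for multi-minimum
sampling experiments.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import constants
from .alf import ALFDefinition, alf_rotation, assign_alf, build_bond_graph
from .chem_io import HessianMatrix, LabeledGeometry, MultipoleSet

__all__ = [
    "SurrogateParams",
    "Fixture",
    "surrogate_moments",
    "surrogate_moments_ensemble",
    "harmonic_pair_hessian",
    "make_fixture",
]

# base moments per element: monopole, dipole (z,x,y), then constant values
# for ranks 2-4 so every rank combination contributes to pair energies
_BASE_MONOPOLE = {"O": -1.0, "C": 0.3, "H": 0.35}
_BASE_TRIATOMIC_MONOPOLE = {"O": -0.7, "H": 0.35}
_BASE_HIGHER = {
    # rank: per-element magnitude (a.u.)
    1: {"O": 0.10, "C": 0.05, "H": 0.02},
    2: {"O": 0.30, "C": 0.15, "H": 0.05},
    3: {"O": 0.10, "C": 0.08, "H": 0.02},
    4: {"O": 0.05, "C": 0.04, "H": 0.01},
}
_RANK_OFFSET = {1: 1, 2: 4, 3: 9, 4: 16}


@dataclasses.dataclass
class SurrogateParams:
    """Frozen parameters of the surrogate moment generator.

    The bond list, reference distances and ALF all come from the seed
    geometry and stay fixed for an ensemble.
    """

    base: np.ndarray                        # (N, 25)
    bonds: list[tuple[int, int]]
    bond_coeffs: np.ndarray                 # (n_bonds,), charge-transfer c_ab
    ref_inv_dist: np.ndarray                # (n_bonds,), 1/r0_ab
    dipole_gain: np.ndarray                 # (N,)
    neighbours: list[list[int]]             # bonded neighbours per atom
    alf: ALFDefinition
    noise: float = 0.0
    seed: int = 0

    @property
    def n_atoms(self) -> int:
        return self.base.shape[0]


def surrogate_moments(
    geom: LabeledGeometry,
    params: SurrogateParams,
    rng: np.random.Generator | None = None,
) -> MultipoleSet:
    """Smooth conformation-dependent ALF-frame moments for one conformer."""
    n = params.n_atoms
    if geom.n_atoms != n:
        raise ValueError("geometry does not match surrogate parameters")
    q = params.base.copy()
    coords = geom.coords
    # bond-wise charge transfer (net charge conserved exactly)
    for (a, b), c, inv0 in zip(params.bonds, params.bond_coeffs, params.ref_inv_dist):
        r = np.linalg.norm(coords[b] - coords[a])
        delta = c * (1.0 / r - inv0)
        q[a, 0] += delta
        q[b, 0] -= delta
    # dipole coupling to neighbour directions in each atom's local frame
    for a in range(n):
        rot = alf_rotation(geom, params.alf, a)
        v = np.zeros(3)
        for b in params.neighbours[a]:
            d = coords[b] - coords[a]
            r = np.linalg.norm(d)
            v += (rot @ (d / r)) / r
        gain = params.dipole_gain[a]
        q[a, 1] += gain * v[2]   # Q10  <- z
        q[a, 2] += gain * v[0]   # Q11c <- x
        q[a, 3] += gain * v[1]   # Q11s <- y
    if params.noise > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        q += rng.normal(scale=params.noise, size=q.shape)
    return MultipoleSet(q, frame="ALF")


def surrogate_moments_ensemble(
    geoms, params: SurrogateParams
) -> list[MultipoleSet]:
    """Moments for a whole ensemble with one seeded noise stream."""
    rng = np.random.default_rng(params.seed) if params.noise > 0 else None
    return [surrogate_moments(g, params, rng) for g in geoms]


# ---------------------------------------------------------------------------
# analytic harmonic fixtures

def harmonic_pair_hessian(geom: LabeledGeometry, k_pairs: np.ndarray) -> HessianMatrix:
    """Exact Hessian of V = 1/2 sum k_ab (r_ab - r0_ab)^2 at its minimum.

    r0_ab is the current distance, so the given geometry is the minimum and
    each pair contributes k_ab (rhat rhat^T) blocks.
    """
    n = geom.n_atoms
    k_pairs = np.asarray(k_pairs, dtype=float)
    h = np.zeros((3 * n, 3 * n))
    for a in range(n):
        for b in range(a + 1, n):
            k = k_pairs[a, b]
            if k == 0.0:
                continue
            d = geom.coords[b] - geom.coords[a]
            u = d / np.linalg.norm(d)
            blk = k * np.outer(u, u)
            h[3 * a:3 * a + 3, 3 * a:3 * a + 3] += blk
            h[3 * b:3 * b + 3, 3 * b:3 * b + 3] += blk
            h[3 * a:3 * a + 3, 3 * b:3 * b + 3] -= blk
            h[3 * b:3 * b + 3, 3 * a:3 * a + 3] -= blk
    return HessianMatrix(h, n)


@dataclasses.dataclass
class Fixture:
    kind: str
    geometries: list[LabeledGeometry]
    hessians: list[HessianMatrix]
    params: SurrogateParams

    @property
    def geometry(self) -> LabeledGeometry:
        return self.geometries[0]

    @property
    def hessian(self) -> HessianMatrix:
        return self.hessians[0]


def _geometry(elements, coords_angstrom, comment) -> LabeledGeometry:
    coords = np.asarray(coords_angstrom, dtype=float) * constants.BOHR_PER_ANGSTROM
    masses = np.array([constants.atomic_mass_me(e) for e in elements])
    return LabeledGeometry(tuple(elements), coords, masses, comment)


def _default_params(geom: LabeledGeometry, monopoles: dict, noise: float, seed: int) -> SurrogateParams:
    graph = build_bond_graph(geom)
    alf = assign_alf(graph, geom.elements)
    n = geom.n_atoms
    base = np.zeros((n, 25))
    for a, e in enumerate(geom.elements):
        base[a, 0] = monopoles[e]
        for rank, off in _RANK_OFFSET.items():
            width = 2 * rank + 1
            mag = _BASE_HIGHER[rank][e]
            # fixed per-component pattern, alternating sign, decaying with m
            base[a, off:off + width] = mag * np.array(
                [(-1.0) ** m / (1.0 + 0.5 * m) for m in range(width)]
            )
    bonds = sorted(tuple(sorted(e)) for e in graph.edges())
    ref_inv = np.array([
        1.0 / np.linalg.norm(geom.coords[b] - geom.coords[a]) for a, b in bonds
    ])
    # charge-transfer coefficient scaled by electronegativity-like contrast
    zval = {"H": 1.0, "C": 4.0, "O": 6.0}
    coeffs = np.array([
        0.8 * (zval[geom.elements[b]] - zval[geom.elements[a]]) / 6.0 + 0.3
        for a, b in bonds
    ])
    gains = np.array([0.25 if e != "H" else 0.10 for e in geom.elements])
    neighbours = [sorted(graph[a]) for a in range(n)]
    return SurrogateParams(
        base=base, bonds=bonds, bond_coeffs=coeffs, ref_inv_dist=ref_inv,
        dipole_gain=gains, neighbours=neighbours, alf=alf, noise=noise, seed=seed,
    )


def _triatomic_coords(bond_angstrom: float, angle_deg: float) -> np.ndarray:
    half = np.radians(angle_deg) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [bond_angstrom * np.sin(half), 0.0, bond_angstrom * np.cos(half)],
        [-bond_angstrom * np.sin(half), 0.0, bond_angstrom * np.cos(half)],
    ])


# standard embedded conformer geometries (angstrom) of the two 16-atom
# tetrose analogues; the detected covalent graph is asserted in the tests
_RING16_ELEMENTS = ["O", "C", "C", "O", "C", "O", "C", "O",
                    "H", "H", "H", "H", "H", "H", "H", "H"]
_RING16_COORDS = [
    [2.2476, -0.7308, 0.2611], [0.8344, -0.6833, 0.3177],
    [0.3564, 0.7568, 0.1399], [0.3649, 1.5164, 1.3477],
    [-1.0478, 0.5284, -0.3724], [-1.9191, 0.2171, 0.7213],
    [-0.8528, -0.6880, -1.2685], [0.2763, -1.4331, -0.7583],
    [2.4574, -1.6769, 0.3461], [0.5078, -1.1081, 1.2741],
    [0.9634, 1.2808, -0.6083], [1.2924, 1.5102, 1.6538],
    [-1.4727, 1.3879, -0.8974], [-1.6843, 0.8587, 1.4234],
    [-1.7249, -1.3478, -1.2897], [-0.5990, -0.3883, -2.2904],
]
_CHAIN16_ELEMENTS = ["O", "C", "C", "O", "C", "O", "C", "O",
                     "H", "H", "H", "H", "H", "H", "H", "H"]
_CHAIN16_COORDS = [
    [2.6625, -1.7130, -0.6112], [1.9548, -0.7286, -0.8239],
    [1.0603, -0.1263, 0.2478], [1.0088, -0.9885, 1.3830],
    [-0.3398, 0.0878, -0.3259], [-0.2925, 1.0672, -1.3758],
    [-1.3314, 0.5693, 0.7382], [-2.5907, 0.8168, 0.1009],
    [1.9840, -0.1998, -1.7919], [1.5131, 0.8254, 0.5467],
    [1.8430, -1.5036, 1.3706], [-0.7224, -0.8370, -0.7749],
    [-1.2106, 1.4044, -1.4545], [-1.0033, 1.5199, 1.1705],
    [-1.4761, -0.1577, 1.5429], [-3.0598, -0.0362, 0.0575],
]


def _pair_constants(geom: LabeledGeometry, graph) -> np.ndarray:
    """Spring constants: stiff on bonds, weak distance-decayed elsewhere."""
    n = geom.n_atoms
    k = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            r = np.linalg.norm(geom.coords[b] - geom.coords[a])
            if graph.has_edge(a, b):
                k[a, b] = k[b, a] = 0.35
            else:
                k[a, b] = k[b, a] = 0.02 * (4.0 / r) ** 2
    return k


def make_fixture(kind: str, noise: float = 0.0, seed: int = 0, n_minima: int = 2) -> Fixture:
    """Build a self-contained (geometry, Hessian, surrogate) test system.

    kind: 'triatomic' (bent water-like molecule, 3 vibrations), 'chain16'
    (open-chain tetrose topology, acyclic, 15 bonds), 'ring16'
    (tetrofuranose topology, one 5-ring, 39 interacting pairs at min_sep 4),
    or 'double_well' (n_minima well-separated triatomic seed minima).
    """
    if kind == "triatomic":
        geoms = [_geometry(["O", "H", "H"], _triatomic_coords(0.96, 104.5), "triatomic")]
        monos = _BASE_TRIATOMIC_MONOPOLE
    elif kind == "double_well":
        if n_minima < 2:
            raise ValueError("double_well needs at least 2 minima")
        geoms = [
            _geometry(
                ["O", "H", "H"],
                _triatomic_coords(0.96 + 0.03 * m, 104.5 - 8.0 * m),
                f"minimum {m}",
            )
            for m in range(n_minima)
        ]
        monos = _BASE_TRIATOMIC_MONOPOLE
    elif kind == "chain16":
        geoms = [_geometry(_CHAIN16_ELEMENTS, _CHAIN16_COORDS, "chain16")]
        monos = _BASE_MONOPOLE
    elif kind == "ring16":
        geoms = [_geometry(_RING16_ELEMENTS, _RING16_COORDS, "ring16")]
        monos = _BASE_MONOPOLE
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    hessians = []
    for g in geoms:
        graph = build_bond_graph(g)
        hessians.append(harmonic_pair_hessian(g, _pair_constants(g, graph)))
    params = _default_params(geoms[0], monos, noise, seed)
    return Fixture(kind, geoms, hessians, params)
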