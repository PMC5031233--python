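"""Bonded-path interaction topology and multipolar electrostatic energies.

Atom pairs interact only when separated by at least ``min_sep`` bonds along
the shortest covalent bond path (default 4, i.e. 1-5 and higher); shorter
paths are excluded to avoid divergence of the point-multipole expansion
between overlapping atomic densities.

The pair energy is the real spherical-tensor multipole expansion truncated
at L = l_A + l_B + 1 <= 5, i.e. up to quadrupole-quadrupole plus the
rank-equivalent dipole-octopole and monopole-hexadecapole combinations:

    E_AB = sum_{l_A + l_B <= 4} Q^A_{l_A m_A} T_{l_A m_A, l_B m_B}(R_AB)
           Q^B_{l_B m_B}

with all quantities in atomic units (energies reported in hartree and
kJ/mol).
"""
from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from . import constants
from .alf import ALFDefinition, rotate_multipole_set
from .chem_io import LabeledGeometry, MultipoleSet
from .solid_harmonics import RANK_SLICES, interaction_block

__all__ = [
    "InteractionTopology",
    "PairEnergyTable",
    "path_separations",
    "interaction_pairs",
    "build_topology",
    "pair_energy",
    "total_electrostatic_energy",
]

L_MAX_DEFAULT = 5
MIN_SEP_DEFAULT = 4


@dataclasses.dataclass
class InteractionTopology:
    path_sep: np.ndarray           # (N, N) shortest bond-path lengths
    pairs: list[tuple[int, int]]   # unordered pairs, separation >= min_sep
    min_sep: int = MIN_SEP_DEFAULT


@dataclasses.dataclass
class PairEnergyTable:
    pairs: list[tuple[int, int]]
    separations: list[int]
    energies: np.ndarray                      # hartree, per pair
    breakdown: list[dict[tuple[int, int], float]]  # (l_A, l_B) -> hartree

    @property
    def total_hartree(self) -> float:
        return float(self.energies.sum())

    @property
    def total_kjmol(self) -> float:
        return self.total_hartree * constants.KJMOL_PER_HARTREE


def path_separations(graph: nx.Graph) -> np.ndarray:
    """All-pairs shortest bond-path lengths (breadth-first)."""
    if not nx.is_connected(graph):
        comps = [sorted(c) for c in nx.connected_components(graph)]
        raise ValueError(f"bond graph disconnected: components {comps}")
    n = graph.number_of_nodes()
    sep = np.zeros((n, n), dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for dst, d in lengths.items():
            sep[src, dst] = d
    return sep


def interaction_pairs(path_sep: np.ndarray, min_sep: int = MIN_SEP_DEFAULT):
    """Unordered atom pairs with bond separation >= min_sep, sorted."""
    n = path_sep.shape[0]
    return [
        (i, j) for i in range(n) for j in range(i + 1, n)
        if path_sep[i, j] >= min_sep
    ]


def build_topology(graph: nx.Graph, min_sep: int = MIN_SEP_DEFAULT) -> InteractionTopology:
    sep = path_separations(graph)
    return InteractionTopology(sep, interaction_pairs(sep, min_sep), min_sep)


def pair_energy(
    q_a: np.ndarray,
    q_b: np.ndarray,
    r_a: np.ndarray,
    r_b: np.ndarray,
    l_max: int = L_MAX_DEFAULT,
) -> tuple[float, dict[tuple[int, int], float]]:
    """Multipole-expansion energy (hartree) between two atoms.

    Moments must be in the global frame; positions in bohr.  Returns the
    total and the per-(l_A, l_B) breakdown, which sums to the total exactly.
    """
    r_ab = np.asarray(r_b, dtype=float) - np.asarray(r_a, dtype=float)
    dist = np.linalg.norm(r_ab)
    if dist == 0.0:
        raise ValueError("coincident atomic positions")
    if not 1 <= l_max <= 5:
        raise ValueError("l_max must be between 1 and 5")
    q_a = np.asarray(q_a, dtype=float)
    q_b = np.asarray(q_b, dtype=float)
    breakdown: dict[tuple[int, int], float] = {}
    for la in range(5):
        for lb in range(5 - la):
            if la + lb + 1 > l_max:
                continue
            t = interaction_block(la, lb, r_ab)
            e = float(q_a[RANK_SLICES[la]] @ t @ q_b[RANK_SLICES[lb]])
            breakdown[(la, lb)] = e
    return sum(breakdown.values()), breakdown


def total_electrostatic_energy(
    moments: MultipoleSet,
    geom: LabeledGeometry,
    topology: InteractionTopology,
    alf: ALFDefinition | None = None,
    l_max: int = L_MAX_DEFAULT,
) -> PairEnergyTable:
    """Sum pair energies over the 1-(min_sep+1) and higher topology.

    ALF-frame moments are rotated into the global frame first (this needs
    the ALF definition); global-frame moments are used as-is.
    """
    if moments.frame == "ALF":
        if alf is None:
            raise ValueError("ALF-frame moments need an ALF definition to rotate")
        moments = rotate_multipole_set(moments, geom, alf, to_frame="global")
    pairs = topology.pairs
    energies = np.empty(len(pairs))
    breakdowns = []
    seps = []
    for k, (i, j) in enumerate(pairs):
        e, bd = pair_energy(
            moments.values[i], moments.values[j], geom.coords[i], geom.coords[j], l_max
        )
        energies[k] = e
        breakdowns.append(bd)
        seps.append(int(topology.path_sep[i, j]))
    return PairEnergyTable(list(pairs), seps, energies, breakdowns)
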