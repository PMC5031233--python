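"""Convergence of the multipolar electrostatic interaction energy.

Two random 4-charge clusters are condensed into rank-4 multipole expansions
about their centroids; the pair energy from the spherical-tensor interaction
(all rank combinations with l1 + l2 <= 4) is compared against the exact
point-charge Coulomb sum as the clusters separate.  Also demonstrates the
interaction topology of the 16-atom furanose surrogate.
"""
import numpy as np

import krigfield as kf
from krigfield.electrostatics import build_topology, pair_energy
from krigfield.solid_harmonics import point_charge_moments

rng = np.random.default_rng(7)
qa, qb = rng.normal(size=4), rng.normal(size=4)
pa, pb = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
pa -= pa.mean(axis=0)
pb -= pb.mean(axis=0)
radius = max(np.linalg.norm(pa, axis=1).max(), np.linalg.norm(pb, axis=1).max())

ma = point_charge_moments(qa, pa)
mb = point_charge_moments(qb, pb)

print("separation / cluster radius   rel. error of multipole energy")
for mult in (5.0, 10.0, 20.0, 40.0):
    rb = np.array([0.0, 0.0, mult * radius])
    e_mp, breakdown = pair_energy(ma, mb, np.zeros(3), rb)
    exact = sum(qa[i] * qb[j] / np.linalg.norm(rb + pb[j] - pa[i])
                for i in range(4) for j in range(4))
    print(f"  {mult:4.0f}x                        "
          f"{abs(e_mp - exact) / abs(exact):.2e}")

# charge-charge term dominates at long range
rb = np.array([0.0, 0.0, 40.0 * radius])
_, breakdown = pair_energy(ma, mb, np.zeros(3), rb)
print("\nrank-combination breakdown at 40x separation (hartree):")
for (l1, l2), e in sorted(breakdown.items()):
    print(f"  l1={l1} l2={l2}: {e:+.3e}")

# interaction topology: pairs 4 or more bonds apart on the furanose ring
fx = kf.make_fixture("ring16")
graph = kf.build_bond_graph(fx.geometry)
topo = build_topology(graph, 4)
print(f"\nfuranose surrogate: {graph.number_of_edges()} bonds, "
      f"{len(topo.pairs)} interacting pairs at >= 4 bond separation")
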