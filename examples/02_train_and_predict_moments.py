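"""Learn conformation-dependent atomic multipole moments by kriging.

End-to-end on the triatomic surrogate: sample an ensemble, build
rotation-invariant atomic-local-frame (ALF) features, train one kriging
model per atom per multipole component, and validate the predictions
through the multipolar electrostatic interaction energy (S-curve).
"""
import numpy as np

import krigfield as kf
from krigfield.alf import assign_alf, build_bond_graph, feature_matrix
from krigfield.pipeline import TrainingConfig, train_models
from krigfield.pso import PSOConfig

fixture = kf.make_fixture("triatomic")
geom = fixture.geometry

# --- sample conformers and evaluate the surrogate "ab initio" moments ----
modes = kf.vibrational_analysis(geom, fixture.hessian)
ensemble = kf.generate(geom, modes, kf.SamplerConfig(n_samples=150, seed=0))
moment_sets = kf.surrogate_moments_ensemble(ensemble, fixture.params)

# --- ALF features: 3N-6 internal coordinates per atom ---------------------
graph = build_bond_graph(geom)
alf = assign_alf(graph, geom.elements)
print("ALF x-axis atoms:", alf.x_axis, " xy-plane atoms:", alf.xy_plane)

train_idx, test_idx = np.arange(100), np.arange(100, 150)

# modest PSO budget: 3-feature problems converge quickly
cfg = TrainingConfig(pso=PSOConfig(swarm_size=15, max_iters=40), fixed_p=2.0)

atom_models = []
for atom in range(geom.n_atoms):
    X = feature_matrix(ensemble, alf, atom)
    Y = np.stack([ms.values[atom] for ms in moment_sets])
    models = train_models(X[train_idx], Y[train_idx], atom, cfg, seed=atom)
    atom_models.append((models, X, Y))
    n_const = sum(m.constant for m in models.models)
    print(f"atom {atom}: {len(models.models)} component models, "
          f"{n_const} constant")

# --- component-level accuracy on held-out conformers ----------------------
for atom, (models, X, Y) in enumerate(atom_models):
    pred = models.predict(X[test_idx])
    err = np.abs(pred - Y[test_idx]).max()
    print(f"atom {atom}: max |moment error| on 50 test conformers = {err:.2e} ea0^l")

# --- energy-level validation: the S-curve ---------------------------------
res = kf.scurve_experiment(
    kf.make_fixture("triatomic"), n_train=100, n_test=50, seed=0,
    sampler=kf.SamplerConfig(n_samples=150), training=cfg, min_sep=1,
)
print(f"\nS-curve over {res.n_test} test conformers:")
print(f"  mean |dE|   = {res.scurve.mean:.4f} kJ/mol")
print(f"  median |dE| = {res.scurve.median:.4f} kJ/mol")
print(f"  max |dE|    = {res.scurve.deviations.max():.4f} kJ/mol")
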