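"""End-to-end experiment drivers: sample -> features -> train -> predict ->
energy -> S-curve.

``train_models`` fits one kriging model per atom per multipole component
(25 per atom; components that are constant over the training set collapse
to flagged constant predictors and cost nothing).  ``predict_moments``
evaluates all models at test conformations, and ``scurve_experiment`` runs
the whole validation loop on a surrogate fixture, reporting the error
S-curve of the total 1-5+ electrostatic energy over a held-out test set.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .alf import ALFDefinition, assign_alf, build_bond_graph, feature_matrix
from .chem_io import LabeledGeometry, MultipoleSet
from .electrostatics import (
    InteractionTopology,
    build_topology,
    total_electrostatic_energy,
)
from .kriging import HyperparamBounds, KrigingModel, fit, predict
from .normal_modes import vibrational_analysis
from .pso import PSOConfig
from .sampler import SamplerConfig, generate_multi
from .surrogate import Fixture, make_fixture, surrogate_moments_ensemble
from .validation import SCurve, s_curve, split

__all__ = [
    "AtomModels",
    "TrainingConfig",
    "train_models",
    "predict_moments",
    "scurve_experiment",
    "ExperimentResult",
]


@dataclasses.dataclass
class TrainingConfig:
    bounds: HyperparamBounds = dataclasses.field(default_factory=HyperparamBounds)
    pso: PSOConfig = dataclasses.field(default_factory=PSOConfig)
    fixed_p: float | None = None
    nugget: float = 1e-10


@dataclasses.dataclass
class AtomModels:
    """The 25 per-component kriging models of one atom."""

    atom: int
    models: list[KrigingModel]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted 25 components for each row of X: shape (m, 25)."""
        return np.column_stack([predict(m, X) for m in self.models])


def train_models(
    features: np.ndarray,
    outputs: np.ndarray,
    atom: int,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
) -> AtomModels:
    """Fit the 25 independent component models of one atom."""
    cfg = cfg or TrainingConfig()
    models = []
    for comp in range(25):
        models.append(
            fit(
                features,
                outputs[:, comp],
                bounds=cfg.bounds,
                pso_cfg=cfg.pso,
                seed=seed + comp,
                nugget=cfg.nugget,
                fixed_p=cfg.fixed_p,
            )
        )
    return AtomModels(atom, models)


def predict_moments(models: list[AtomModels], features_per_atom) -> list[MultipoleSet]:
    """ALF-frame moment sets for every test conformation.

    features_per_atom[a] is the (m, 3N-6) feature matrix of atom a.
    """
    n_atoms = len(models)
    per_atom = [models[a].predict(features_per_atom[a]) for a in range(n_atoms)]
    m = per_atom[0].shape[0]
    return [
        MultipoleSet(np.vstack([per_atom[a][i] for a in range(n_atoms)]), frame="ALF")
        for i in range(m)
    ]


@dataclasses.dataclass
class ExperimentResult:
    scurve: SCurve
    n_train: int
    n_test: int
    alf: ALFDefinition
    topology: InteractionTopology


def scurve_experiment(
    fixture: Fixture,
    n_train: int,
    n_test: int,
    seed: int,
    sampler: SamplerConfig | None = None,
    training: TrainingConfig | None = None,
    min_sep: int = 4,
    ensemble: list[LabeledGeometry] | None = None,
) -> ExperimentResult:
    """One full surrogate validation run.

    Samples an ensemble around the fixture's seed minima (unless one is
    supplied), computes surrogate reference moments, trains per-atom kriging
    models on a train split, predicts moments for the test split and
    compares total 1-(min_sep+1)+ electrostatic energies, in kJ/mol.
    """
    training = training or TrainingConfig()
    if ensemble is None:
        sampler = sampler or SamplerConfig()
        n_total = max(sampler.n_samples, n_train + n_test)
        sampler = dataclasses.replace(sampler, n_samples=n_total, seed=seed)
        seeds = [
            (g, vibrational_analysis(g, h))
            for g, h in zip(fixture.geometries, fixture.hessians)
        ]
        ensemble = generate_multi(seeds, sampler)
    graph = build_bond_graph(fixture.geometry)
    alf = assign_alf(graph, fixture.geometry.elements)
    topology = build_topology(graph, min_sep)

    moments = surrogate_moments_ensemble(ensemble, fixture.params)
    train_idx, test_idx = split(len(ensemble), n_train, n_test, seed)
    train_geoms = [ensemble[i] for i in train_idx]
    test_geoms = [ensemble[i] for i in test_idx]

    n_atoms = fixture.geometry.n_atoms
    feats_train = [feature_matrix(train_geoms, alf, a) for a in range(n_atoms)]
    feats_test = [feature_matrix(test_geoms, alf, a) for a in range(n_atoms)]
    outputs = np.stack([m.values for m in moments])  # (n_total, N, 25)

    models = [
        train_models(feats_train[a], outputs[train_idx, a, :], a, training, seed=seed)
        for a in range(n_atoms)
    ]
    predicted = predict_moments(models, feats_test)

    pred_e, ref_e = [], []
    for i, g in enumerate(test_geoms):
        ref = MultipoleSet(outputs[test_idx[i]], frame="ALF")
        e_ref = total_electrostatic_energy(ref, g, topology, alf)
        e_pred = total_electrostatic_energy(predicted[i], g, topology, alf)
        ref_e.append(e_ref.total_kjmol)
        pred_e.append(e_pred.total_kjmol)
    return ExperimentResult(
        s_curve(pred_e, ref_e), n_train, n_test, alf, topology
    )
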