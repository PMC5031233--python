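"""Train/test splitting, S-curves, learning-curve fits and extrapolation flags.

An S-curve is the empirical cumulative distribution of absolute prediction
errors of the total electrostatic energy over a test set: the difference
between predicted and reference energy is taken per configuration and only
then the absolute value, so errors never cancel across configurations.
Percentiles use the inclusive (<=) empirical convention.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SCurve",
    "LearningCurveFit",
    "split",
    "s_curve",
    "percentile_below",
    "fit_learning_curve",
    "flag_extrapolation",
]


@dataclasses.dataclass
class SCurve:
    deviations: np.ndarray   # sorted ascending, kJ/mol (or caller's unit)
    percentiles: np.ndarray  # inclusive empirical percentile of each deviation
    mean: float
    median: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"deviation_kJmol": self.deviations, "percentile": self.percentiles}
        ).to_csv(path, index=False)


@dataclasses.dataclass
class LearningCurveFit:
    """Least-squares fits of mean error against training size n."""

    A: float  # error ~ A + B/n
    B: float
    r2_inverse: float
    C: float  # error ~ C + D/sqrt(n)
    D: float
    r2_inverse_sqrt: float


def split(n_total: int, n_train: int, n_test: int, seed: int):
    """Disjoint train/test index arrays, deterministic given seed."""
    if n_train + n_test > n_total:
        raise ValueError(
            f"cannot draw {n_train}+{n_test} from {n_total} samples"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:n_train + n_test])


def s_curve(pred_energies, ref_energies) -> SCurve:
    pred = np.asarray(pred_energies, dtype=float)
    ref = np.asarray(ref_energies, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("predicted and reference energies must be equal-length 1-D")
    dev = np.sort(np.abs(pred - ref))
    n = dev.size
    pct = 100.0 * np.arange(1, n + 1) / n
    return SCurve(dev, pct, float(dev.mean()), float(np.median(dev)))


def percentile_below(scurve: SCurve, threshold: float) -> float:
    """Percent of test configurations with deviation <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return 100.0 * float(np.mean(scurve.deviations <= threshold))


def fit_learning_curve(ns, mean_errors) -> LearningCurveFit:
    """Fit mean error against training size with A + B/n and C + D/sqrt(n)."""
    ns = np.asarray(ns, dtype=float)
    err = np.asarray(mean_errors, dtype=float)
    if ns.size < 3:
        raise ValueError("need at least 3 (n, error) points")
    if np.ptp(ns) == 0:
        raise ValueError("all training sizes are equal")

    def r2(y, yhat):
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    (a, b), _ = curve_fit(lambda n, A, B: A + B / n, ns, err)
    (c, d), _ = curve_fit(lambda n, C, D: C + D / np.sqrt(n), ns, err)
    return LearningCurveFit(
        A=float(a), B=float(b), r2_inverse=float(r2(err, a + b / ns)),
        C=float(c), D=float(d), r2_inverse_sqrt=float(r2(err, c + d / np.sqrt(ns))),
    )


def flag_extrapolation(train_features: np.ndarray, query_feature: np.ndarray):
    """Flag a query lying outside the training cloud.

    The query is flagged when its Euclidean distance to the nearest
    training point exceeds the 99th percentile of the training set's own
    nearest-neighbour distances.  Returns (flag, distance).
    """
    X = np.asarray(train_features, dtype=float)
    q = np.asarray(query_feature, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    d_q = np.linalg.norm(X - q, axis=1)
    dist = float(d_q.min())
    pair = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(pair, np.inf)
    nn = pair.min(axis=1)
    threshold = float(np.percentile(nn, 99))
    return dist > threshold, dist
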