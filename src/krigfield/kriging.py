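"""Kriging (Gaussian-process) regression with the p-exponential kernel.

The correlation between feature vectors x_i, x_j is

    R(x_i, x_j) = exp(-sum_h theta_h |x_h^i - x_h^j|^{p_h}),

with per-dimension hyperparameters theta_h > 0 and p_h in [1, 2].  The
process mean and variance are profiled out analytically,

    mu_hat    = (1' R^-1 y) / (1' R^-1 1)
    sigma2    = (y - 1 mu)' R^-1 (y - 1 mu) / n
    log L     = -(n/2) ln sigma2 - (1/2) ln |R|,

and the concentrated log-likelihood is maximized over (theta, p) by
particle swarm optimization, with theta searched in log10 space.
Predictions are y_hat(x*) = mu_hat + sum_i a_i R(x*, x_i) with
a = R^-1 (y - 1 mu_hat).

A small nugget (default 1e-10, escalated tenfold up to 1e-6 on Cholesky
failure) regularizes the correlation matrix against near-duplicate rows and
integration noise in the observations.  Constant outputs (e.g. a
symmetry-fixed moment component) cannot support a likelihood and are
replaced by a flagged constant predictor.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .pso import PSOConfig, maximize

__all__ = [
    "KrigingHyperparams",
    "KrigingModel",
    "HyperparamBounds",
    "DegenerateOutputError",
    "ConditioningError",
    "correlation",
    "correlation_matrix",
    "concentrated_log_likelihood",
    "fit",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_NUGGET = 1e-10
MAX_NUGGET = 1e-6


class DegenerateOutputError(ValueError):
    """Outputs are constant: the concentrated likelihood is undefined."""


class ConditioningError(np.linalg.LinAlgError):
    """Correlation matrix not positive definite even at the maximum nugget."""


@dataclasses.dataclass
class KrigingHyperparams:
    theta: np.ndarray  # (d,) positive
    p: np.ndarray      # (d,) in [1, 2]

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.theta.shape != self.p.shape:
            raise ValueError("theta and p must have equal dimension")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be positive")
        if np.any((self.p < 1) | (self.p > 2)):
            raise ValueError("p must lie in [1, 2]")


@dataclasses.dataclass
class HyperparamBounds:
    """Search box: theta in log10 space, p linear."""

    log10_theta: tuple[float, float] = (-6.0, 3.0)
    p: tuple[float, float] = (1.0, 2.0)


@dataclasses.dataclass
class KrigingModel:
    X: np.ndarray
    y: np.ndarray
    hyperparams: KrigingHyperparams | None
    mu: float
    sigma2: float
    a: np.ndarray | None
    nugget: float
    constant: bool = False  # flagged constant predictor for degenerate y
    log_likelihood: float = np.nan

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def correlation(x_i: np.ndarray, x_j: np.ndarray, theta, p) -> float:
    """Pairwise p-exponential correlation in (0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("feature dimension mismatch")
    hp = KrigingHyperparams(np.broadcast_to(theta, x_i.shape).copy(),
                            np.broadcast_to(p, x_i.shape).copy())
    return float(np.exp(-np.sum(hp.theta * np.abs(x_i - x_j) ** hp.p)))


def _abs_diff_tensor(X: np.ndarray) -> np.ndarray:
    """|x_h^i - x_h^j| stacked per dimension: shape (d, n, n)."""
    return np.abs(X[:, None, :] - X[None, :, :]).transpose(2, 0, 1)


def _corr_from_diffs(diffs: np.ndarray, theta: np.ndarray, p: np.ndarray) -> np.ndarray:
    d = theta.size
    if np.all(p == 2.0):
        expo = np.tensordot(theta, diffs * diffs, axes=(0, 0))
    else:
        expo = np.tensordot(theta, diffs ** p[:, None, None], axes=(0, 0))
    return np.exp(-expo)


def correlation_matrix(
    X: np.ndarray, theta, p, nugget: float = DEFAULT_NUGGET
):
    """Correlation matrix with nugget and its Cholesky factorization.

    Returns (R, cho, nugget_used).  On factorization failure the nugget is
    escalated tenfold up to 1e-6; beyond that a ConditioningError reports
    the closest (near-duplicate) training rows.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training points")
    hp = KrigingHyperparams(np.broadcast_to(theta, X.shape[1]).copy(),
                            np.broadcast_to(p, X.shape[1]).copy())
    diffs = _abs_diff_tensor(X)
    R0 = _corr_from_diffs(diffs, hp.theta, hp.p)
    nug = nugget
    while True:
        R = R0 + nug * np.eye(n)
        try:
            cho = cho_factor(R, lower=True)
            return R, cho, nug
        except LinAlgError:
            if nug == 0.0:
                nug = DEFAULT_NUGGET
            elif nug < MAX_NUGGET:
                nug = min(nug * 10.0, MAX_NUGGET)
            else:
                off = R0 - np.eye(n)
                i, j = np.unravel_index(np.argmax(off), off.shape)
                raise ConditioningError(
                    "correlation matrix not positive definite at nugget "
                    f"{MAX_NUGGET}; closest training rows: {min(i, j)} and "
                    f"{max(i, j)} (correlation {off[i, j]:.6f})"
                ) from None


def _profiled(cho, y: np.ndarray):
    n = y.size
    ones = np.ones(n)
    ri_y = cho_solve(cho, y)
    ri_1 = cho_solve(cho, ones)
    mu = (ones @ ri_y) / (ones @ ri_1)
    resid = y - mu
    ri_r = ri_y - mu * ri_1
    sigma2 = (resid @ ri_r) / n
    return mu, sigma2, ri_r


def concentrated_log_likelihood(
    theta, p, X: np.ndarray, y: np.ndarray, nugget: float = DEFAULT_NUGGET
) -> float:
    """-(n/2) ln sigma2_hat - (1/2) ln |R| with mu, sigma2 profiled out."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.ptp(y) == 0.0:
        raise DegenerateOutputError("outputs are constant")
    _, cho, _ = correlation_matrix(X, theta, p, nugget)
    mu, sigma2, _ = _profiled(cho, y)
    if sigma2 < 1e-300:
        raise DegenerateOutputError("profiled variance underflowed (constant outputs)")
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return -(n / 2.0) * np.log(sigma2) - 0.5 * logdet


def fit(
    X: np.ndarray,
    y: np.ndarray,
    bounds: HyperparamBounds | None = None,
    pso_cfg: PSOConfig | None = None,
    seed: int = 0,
    nugget: float = DEFAULT_NUGGET,
    fixed_p: float | None = None,
) -> KrigingModel:
    """Fit hyperparameters by maximizing the concentrated log-likelihood.

    theta is searched in log10 space.  ``fixed_p`` pins every p_h (halving
    the search dimension); otherwise p is searched per dimension in
    bounds.p.  Constant outputs yield a flagged constant predictor instead
    of a likelihood fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, d) and y (n,)")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 training points")
    if np.ptp(y) == 0.0:
        return KrigingModel(
            X=X, y=y, hyperparams=None, mu=float(y[0]), sigma2=0.0,
            a=None, nugget=0.0, constant=True,
        )
    if n < 10 * d:
        warnings.warn(
            f"training set of {n} points is below the 10 x d = {10 * d} "
            "heuristic for reliable hyperparameter estimation",
            stacklevel=2,
        )
    bounds = bounds or HyperparamBounds()
    pso_cfg = pso_cfg or PSOConfig(seed=seed)
    if pso_cfg.seed != seed:
        pso_cfg = dataclasses.replace(pso_cfg, seed=seed)

    diffs = _abs_diff_tensor(X)
    eye = np.eye(n)
    sq_flat = (
        np.ascontiguousarray((diffs * diffs).reshape(d, n * n))
        if fixed_p == 2.0
        else None
    )

    def loglik(theta: np.ndarray, p: np.ndarray) -> float:
        if sq_flat is not None:
            R = np.exp(-(theta @ sq_flat).reshape(n, n)) + nugget * eye
        else:
            R = _corr_from_diffs(diffs, theta, p) + nugget * eye
        try:
            cho = cho_factor(R, lower=True)
        except LinAlgError:
            return -np.inf
        _, sigma2, _ = _profiled(cho, y)
        if sigma2 < 1e-300:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return -(n / 2.0) * np.log(sigma2) - 0.5 * logdet

    if fixed_p is None:
        lower = np.concatenate([np.full(d, bounds.log10_theta[0]), np.full(d, bounds.p[0])])
        upper = np.concatenate([np.full(d, bounds.log10_theta[1]), np.full(d, bounds.p[1])])

        def objective(v):
            return loglik(10.0 ** v[:d], v[d:])
    else:
        p_fixed = np.full(d, float(fixed_p))
        lower = np.full(d, bounds.log10_theta[0])
        upper = np.full(d, bounds.log10_theta[1])

        def objective(v):
            return loglik(10.0 ** v, p_fixed)

    x_best, f_best, _ = maximize(objective, lower, upper, pso_cfg)
    if fixed_p is None:
        theta, p = 10.0 ** x_best[:d], x_best[d:]
    else:
        theta, p = 10.0 ** x_best, np.full(d, float(fixed_p))

    hp = KrigingHyperparams(theta, p)
    R, cho, nug = correlation_matrix(X, hp.theta, hp.p, nugget)
    mu, sigma2, a = _profiled(cho, y)
    # one step of iterative refinement: near-singular R (smooth data, tiny
    # theta, zero nugget) otherwise degrades training-point interpolation
    a = a + cho_solve(cho, (y - mu) - R @ a)
    return KrigingModel(
        X=X, y=y, hyperparams=hp, mu=float(mu), sigma2=float(sigma2),
        a=a, nugget=nug, log_likelihood=float(f_best),
    )


def predict(model: KrigingModel, x_star: np.ndarray) -> np.ndarray:
    """Predict at one point (d,) or a batch (m, d)."""
    x_star = np.asarray(x_star, dtype=float)
    single = x_star.ndim == 1
    pts = np.atleast_2d(x_star)
    if pts.shape[1] != model.d:
        raise ValueError(f"expected {model.d}-dimensional inputs, got {pts.shape[1]}")
    if model.constant:
        out = np.full(pts.shape[0], model.mu)
        return out[0] if single else out
    hp = model.hyperparams
    diff = np.abs(pts[:, None, :] - model.X[None, :, :])
    if np.all(hp.p == 2.0):
        expo = (diff * diff) @ hp.theta
    else:
        expo = (diff ** hp.p[None, None, :]) @ hp.theta
    phi = np.exp(-expo)
    out = model.mu + phi @ model.a
    return out[0] if single else out


def save_model(model: KrigingModel, path, metadata: dict | None = None) -> None:
    """Serialize a model to JSON (plain text, exact float round trip)."""
    import json

    doc = {
        "n": model.n,
        "d": model.d,
        "X": model.X.tolist(),
        "y": model.y.tolist(),
        "mu": model.mu,
        "sigma2": model.sigma2,
        "nugget": model.nugget,
        "constant": model.constant,
        "log_likelihood": model.log_likelihood
        if np.isfinite(model.log_likelihood) else None,
        "metadata": metadata or {},
    }
    if not model.constant:
        doc["theta"] = model.hyperparams.theta.tolist()
        doc["p"] = model.hyperparams.p.tolist()
        doc["a"] = model.a.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> KrigingModel:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    constant = doc["constant"]
    ll = doc.get("log_likelihood")
    return KrigingModel(
        X=np.asarray(doc["X"], dtype=float),
        y=np.asarray(doc["y"], dtype=float),
        hyperparams=None if constant else KrigingHyperparams(
            np.asarray(doc["theta"]), np.asarray(doc["p"])
        ),
        mu=doc["mu"],
        sigma2=doc["sigma2"],
        a=None if constant else np.asarray(doc["a"], dtype=float),
        nugget=doc["nugget"],
        constant=constant,
        log_likelihood=np.nan if ll is None else ll,
    )
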