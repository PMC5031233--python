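import numpy as np
import pytest

from krigfield.kriging import (
    ConditioningError,
    DegenerateOutputError,
    HyperparamBounds,
    KrigingHyperparams,
    concentrated_log_likelihood,
    correlation,
    correlation_matrix,
    fit,
    load_model,
    predict,
    save_model,
)
from krigfield.pso import PSOConfig

FAST_PSO = PSOConfig(swarm_size=15, max_iters=40, seed=0)


class TestCorrelation:
    def test_hand_value(self):
        r = correlation([0.0, 0.0], [1.0, 2.0], theta=[0.5, 0.25], p=[2.0, 1.0])
        assert np.isclose(r, np.exp(-(0.5 * 1.0 + 0.25 * 2.0)), rtol=1e-14)

    def test_identical_points_correlate_fully(self):
        assert correlation([1.0, 2.0], [1.0, 2.0], 1.0, 2.0) == 1.0

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            KrigingHyperparams(np.array([-1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            KrigingHyperparams(np.array([1.0]), np.array([2.5]))


class TestCorrelationMatrix:
    def test_diagonal_is_one_plus_nugget(self):
        X = np.linspace(0, 1, 5)[:, None]
        R, _, nug = correlation_matrix(X, 1.0, 2.0, nugget=1e-8)
        assert np.allclose(np.diag(R), 1.0 + 1e-8)
        assert nug == 1e-8

    def test_large_theta_approaches_identity(self):
        X = np.array([[0.0], [1.0], [2.0]])
        R, _, _ = correlation_matrix(X, 1e6, 2.0, nugget=0.0)
        off = R - np.diag(np.diag(R))
        assert np.abs(off).max() < 1e-12

    def test_duplicate_rows_escalate_nugget(self):
        X = np.array([[0.5], [0.5], [1.0]])
        _, _, nug = correlation_matrix(X, 1.0, 2.0, nugget=0.0)
        assert nug > 0.0  # singular at nugget 0, regularized automatically

    def test_conditioning_error_names_closest_rows(self, monkeypatch):
        # force every factorization attempt to fail so escalation exhausts
        import krigfield.kriging as kg

        def boom(*a, **k):
            raise kg.LinAlgError("no")

        monkeypatch.setattr(kg, "cho_factor", boom)
        X = np.array([[0.0], [1e-9], [5.0]])
        with pytest.raises(ConditioningError, match="rows: 0 and 1"):
            correlation_matrix(X, 1.0, 2.0)


class TestConcentratedLogLikelihood:
    def test_two_point_closed_form(self):
        # X = {0, 1}, y = {-1, 1}, theta = 1, p = 2, nugget 0:
        # R12 = exp(-1), mu = 0, sigma^2 = 1/(1 - exp(-1)),
        # logL = -ln sigma^2 - 0.5 ln(1 - exp(-2))
        e1 = np.exp(-1.0)
        ref = -np.log(1.0 / (1.0 - e1)) - 0.5 * np.log(1.0 - e1 * e1)
        val = concentrated_log_likelihood(
            np.array([1.0]), np.array([2.0]),
            np.array([[0.0], [1.0]]), np.array([-1.0, 1.0]), nugget=0.0,
        )
        assert abs(val - ref) < 1e-6
        assert abs(val - (-0.3859684164526524)) < 1e-12  # frozen numeric oracle

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(12, 3))
        y = np.sin(X @ np.array([1.0, 2.0, 3.0]))
        theta, p = np.array([1.0, 0.5, 2.0]), np.array([2.0, 2.0, 1.5])
        base = concentrated_log_likelihood(theta, p, X, y)
        perm = rng.permutation(12)
        shuffled = concentrated_log_likelihood(theta, p, X[perm], y[perm])
        assert abs(base - shuffled) < 1e-10

    def test_constant_outputs_rejected(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(DegenerateOutputError):
            concentrated_log_likelihood(
                np.array([1.0]), np.array([2.0]), X, np.array([3.0, 3.0])
            )


class TestFit:
    def test_interpolates_training_points(self):
        X = np.linspace(0.0, 1.0, 20)[:, None]
        y = X[:, 0].copy()
        model = fit(X, y, pso_cfg=FAST_PSO, nugget=0.0)
        assert np.isfinite(model.mu)
        yhat = predict(model, X)
        assert np.abs(yhat - y).max() < 1e-8

    def test_constant_outputs_become_flagged_constant_model(self):
        X = np.linspace(0.0, 1.0, 8)[:, None]
        model = fit(X, np.full(8, 2.5), pso_cfg=FAST_PSO)
        assert model.constant
        assert np.all(predict(model, np.array([[0.3], [9.9]])) == 2.5)

    def test_fixed_p_pins_every_exponent(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(25, 2))
        y = np.cos(3 * X[:, 0]) + X[:, 1]
        model = fit(X, y, pso_cfg=FAST_PSO, fixed_p=2.0)
        assert np.all(model.hyperparams.p == 2.0)

    def test_reported_likelihood_matches_recomputation(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(15, 2))
        y = np.sin(4 * X[:, 0]) * X[:, 1]
        model = fit(X, y, pso_cfg=FAST_PSO, nugget=1e-10)
        recomputed = concentrated_log_likelihood(
            model.hyperparams.theta, model.hyperparams.p, X, y, nugget=1e-10
        )
        assert abs(model.log_likelihood - recomputed) < 1e-8

    def test_fit_beats_random_probes(self):
        # sanity bound: the PSO optimum is at least as good as seeded random
        # hyperparameter draws
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(30, 2))
        y = np.sin(5 * X[:, 0]) + 0.3 * X[:, 1] ** 2
        bounds = HyperparamBounds()
        model = fit(X, y, bounds=bounds, pso_cfg=FAST_PSO, nugget=1e-10)
        probe_rng = np.random.default_rng(99)
        for _ in range(100):
            lt = probe_rng.uniform(*bounds.log10_theta, size=2)
            pp = probe_rng.uniform(*bounds.p, size=2)
            val = concentrated_log_likelihood(10.0 ** lt, pp, X, y, nugget=1e-10)
            assert model.log_likelihood >= val - 1e-9

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            fit(np.zeros((4, 2)), np.zeros(5))


class TestPredict:
    def test_batch_equals_single(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(18, 2))
        y = X[:, 0] ** 2 - X[:, 1]
        model = fit(X, y, pso_cfg=FAST_PSO)
        pts = rng.uniform(size=(4, 2))
        batch = predict(model, pts)
        singles = np.array([predict(model, p) for p in pts])
        assert np.allclose(batch, singles, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        X = np.linspace(0, 1, 10)[:, None]
        model = fit(X, X[:, 0], pso_cfg=FAST_PSO)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 3)))

    def test_prediction_reverts_to_mean_far_away(self):
        X = np.linspace(0.0, 1.0, 15)[:, None]
        y = np.sin(2 * np.pi * X[:, 0])
        model = fit(X, y, pso_cfg=FAST_PSO, fixed_p=2.0)
        far = predict(model, np.array([1e6]))
        assert np.isclose(far, model.mu, atol=1e-10)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        model = fit(X, y, pso_cfg=FAST_PSO)
        path = tmp_path / "m.json"
        save_model(model, path, metadata={"atom": 1})
        back = load_model(path)
        pts = rng.uniform(size=(5, 3))
        assert np.array_equal(predict(model, pts), predict(back, pts))

    def test_constant_model_round_trip(self, tmp_path):
        X = np.linspace(0, 1, 5)[:, None]
        model = fit(X, np.full(5, -1.5), pso_cfg=FAST_PSO)
        path = tmp_path / "c.json"
        save_model(model, path)
        back = load_model(path)
        assert back.constant
        assert predict(back, np.array([0.7])) == -1.5
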