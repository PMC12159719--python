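"""OLS/ridge closed forms, network training rules and hyperparameter search."""

import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import Ridge

from envgp import models
from envgp.models import (
    DivergenceError,
    LinearModel,
    NetworkHyperparams,
    NetworkModel,
    choose_ridge_lambda,
    fit_network,
    fit_ols,
    fit_ridge,
    sample_hyperparams,
    should_stop,
    tune_network,
)


class TestOls:
    def test_exact_interpolation(self):
        X = np.array([[1.0], [2.0], [3.0]])
        m = fit_ols(X, 2 * X[:, 0] + 1)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)
        assert m.coef[0] == pytest.approx(2.0, abs=1e-10)

    def test_constant_response_minimum_norm(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        m = fit_ols(X, np.full(10, 3.5))
        assert np.allclose(m.coef, 0.0, atol=1e-10)
        assert m.intercept == pytest.approx(3.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = fit_ols(X, y)
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(m.coef, beta[1:], atol=1e-8)

    def test_residuals_orthogonal_to_columns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        m = fit_ols(X, y)
        r = y - m.predict(X)
        assert np.linalg.norm(X.T @ r) < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_ols(np.empty((0, 2)), np.empty(0))


class TestRidge:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        a, b = fit_ridge(X, y, 0.0), fit_ols(X, y)
        assert np.allclose(a.coef, b.coef, atol=1e-8)

    def test_infinite_penalty_predicts_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = fit_ridge(X, y, 1e9)
        assert np.abs(m.coef).max() < 1e-6
        assert np.allclose(m.predict(X), y.mean(), atol=1e-4)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        lam = 3.7
        m = fit_ridge(X, y, lam)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(50), Xc.T @ yc)
        assert np.allclose(m.coef, beta, atol=1e-8)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        for lam in (0.1, 10.0):
            ours = fit_ridge(X, y, lam)
            sk = Ridge(alpha=lam, solver="svd").fit(X, y)
            assert np.allclose(ours.coef, sk.coef_, atol=1e-6)
            assert ours.intercept == pytest.approx(sk.intercept_, abs=1e-6)

    def test_coefficient_norm_non_increasing_in_penalty(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(15, 6))
            y = rng.normal(size=15)
            norms = [np.linalg.norm(fit_ridge(X, y, lam).coef)
                     for lam in (0.0, 0.1, 1.0, 10.0, 100.0)]
            assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(np.ones((3, 1)), np.ones(3), -1.0)

    def test_lambda_cv_is_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=30)
        assert choose_ridge_lambda(X, y, seed=5) == choose_ridge_lambda(X, y,
                                                                        seed=5)


class TestStoppingRule:
    def test_fires_on_slowing_small_decrease(self):
        assert should_stop([10.0, 9.8, 9.7])

    def test_holds_while_decrease_is_fast_or_accelerating(self):
        assert not should_stop([10.0, 9.0, 7.0])     # accelerating decrements
        assert not should_stop([10.0, 8.0, 6.5])     # slowing but > 5%
        assert not should_stop([10.0, 9.8, 9.9])     # loss rose
        assert not should_stop([10.0, 9.8])          # too short


class TestNetwork:
    def test_learns_linear_signal_better_than_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 10))
        beta = rng.normal(size=10)
        hp = NetworkHyperparams(0.01, 32, 3, 16)
        for seed in range(5):
            y = X @ beta + 0.1 * rng.normal(size=150)
            net = fit_network(X, y, hp, seed=seed)
            assert net.loss_history[-1] < np.var(y)

    def test_reproducible_loss_log_under_fixed_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        hp = NetworkHyperparams(0.01, 16, 3, 8)
        a = fit_network(X, y, hp, seed=3)
        b = fit_network(X, y, hp, seed=3)
        assert a.loss_history == b.loss_history

    def test_epoch_cap_reached_on_hard_instance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        hp = NetworkHyperparams(2.0, 4, 3, 10)
        net = fit_network(X, y, hp, seed=0)
        assert len(net.loss_history) == models.MAX_EPOCHS

    def test_divergence_raises_with_epoch(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 5))
        # response so large that the squared-error loss overflows float64
        y = rng.normal(size=40) * 1e200
        hp = NetworkHyperparams(100.0, 4, 8, 100)
        with pytest.raises(DivergenceError):
            fit_network(X, y, hp, seed=0)

    def test_zero_network_predicts_zero(self):
        net = NetworkModel(
            weights=[np.zeros((2, 3)), np.zeros((3, 1))],
            biases=[np.zeros(3), np.zeros(1)],
            x_mean=np.zeros(2), x_sd=np.ones(2), loss_history=[0.0],
        )
        assert np.allclose(net.predict(np.ones((4, 2))), 0.0)

    def test_hand_built_relu_identity(self):
        # one hidden unit wired so output = ReLU(x)
        net = NetworkModel(
            weights=[np.array([[1.0]]), np.array([[1.0]])],
            biases=[np.zeros(1), np.zeros(1)],
            x_mean=np.zeros(1), x_sd=np.ones(1), loss_history=[0.0],
        )
        x = np.array([[-2.0], [0.5], [3.0]])
        assert np.allclose(net.predict(x), np.maximum(x[:, 0], 0.0))

    def test_linear_predict_arithmetic(self):
        m = LinearModel(intercept=1.0, coef=np.array([2.0]))
        assert m.predict(np.array([[3.0]]))[0] == pytest.approx(7.0)
        with pytest.raises(ValueError):
            m.predict(np.ones((2, 3)))

    def test_serialization_round_trip(self, tmp_path):
        m = LinearModel(1.5, np.array([0.5, -2.0]), lam=3.0)
        models.save_model(m, tmp_path / "m.json")
        m2 = models.load_model(tmp_path / "m.json")
        assert np.allclose(m2.coef, m.coef) and m2.lam == 3.0


class TestHyperparamSearch:
    def test_draws_respect_bounds(self):
        draws = sample_hyperparams(1000, seed=2)
        assert all(1e-4 <= d.learning_rate <= 100 for d in draws)
        assert all(d.batch_size in (4, 8, 16, 32, 64, 128) for d in draws)
        assert all(3 <= d.n_layers <= 8 for d in draws)
        assert all(3 <= d.layer_width <= 100 for d in draws)

    def test_log_learning_rate_uniform(self):
        lr = np.log10([d.learning_rate for d in sample_hyperparams(4000, seed=0)])
        assert stats.kstest(lr, stats.uniform(loc=-4, scale=6).cdf).pvalue > 0.01

    def test_single_draw_tuning_returns_it(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        only = sample_hyperparams(1, seed=6)[0]
        assert tune_network(X, y, n_draws=1, seed=6, max_epochs=3) == only

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            tune_network(np.ones((2, 1)), np.ones(2), n_draws=1, k=3)
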