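"""Gaussian process implementation against dense linear-algebra oracles,
analytic limits and an independent reference implementation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitwalker import gpr
from gaitwalker.gpr import (
    GPHyperparams,
    OptimizerSettings,
    chronological_split,
    condition,
    crossvalidate,
    evaluate,
    fit,
    kernel_matrix,
    log_marginal_likelihood,
    predict,
    rbf_kernel,
)

HP = GPHyperparams(signal_variance=2.0, length_scale=1.5,
                   noise_variance=0.1, constant_mean=0.5)


# ------------------------------------------------------------------- oracles

def oracle_lml(hp, x, y):
    """Direct dense-inverse/determinant evaluation of the log evidence."""
    x = np.asarray(x, float)
    yc = np.asarray(y, float) - hp.constant_mean
    n = x.size
    K = np.array([[rbf_kernel(a, b, hp) for b in x] for a in x])
    Ky = K + hp.noise_variance * np.eye(n)
    sign, logdet = np.linalg.slogdet(Ky)
    assert sign > 0
    return float(-0.5 * yc @ np.linalg.inv(Ky) @ yc - 0.5 * logdet
                 - 0.5 * n * np.log(2 * np.pi))


def oracle_predict(hp, x, y, xs):
    x = np.asarray(x, float)
    yc = np.asarray(y, float) - hp.constant_mean
    Ky = np.array([[rbf_kernel(a, b, hp) for b in x] for a in x]) \
        + hp.noise_variance * np.eye(x.size)
    Kinv = np.linalg.inv(Ky)
    mus, vars_ = [], []
    for q in np.atleast_1d(xs):
        ks = np.array([rbf_kernel(q, b, hp) for b in x])
        mus.append(ks @ Kinv @ yc + hp.constant_mean)
        vars_.append(rbf_kernel(q, q, hp) - ks @ Kinv @ ks)
    return np.array(mus), np.array(vars_)


# -------------------------------------------------------------------- kernel

class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        assert rbf_kernel(3.0, 3.0, HP) == pytest.approx(2.0)

    def test_analytic_value(self):
        hp = GPHyperparams(2.0, 1.0, 0.0)
        assert rbf_kernel(0.0, 1.0, hp) == pytest.approx(2.0 * np.exp(-0.5), rel=1e-12)

    def test_long_range_decay(self):
        hp = GPHyperparams(5.0, 1.0, 0.0)
        assert rbf_kernel(0.0, 100.0, hp) < 1e-3 * 5.0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12, unique=True),
           st.floats(0.1, 10), st.floats(0.1, 10))
    def test_kernel_matrix_symmetric_psd(self, xs, sf2, l):
        hp = GPHyperparams(sf2, l, 0.0)
        K = kernel_matrix(xs, xs, hp)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert w.min() >= -1e-8 * sf2

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            GPHyperparams(-1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            GPHyperparams(1.0, 0.0, 0.1)


# ------------------------------------------------------- marginal likelihood

class TestLogMarginalLikelihood:
    def test_single_point_analytic(self):
        # centered y = 0 and total variance 1: -0.5 log(2 pi)
        hp = GPHyperparams(0.6, 1.0, 0.4, constant_mean=2.0)
        got = log_marginal_likelihood(hp, [0.0], [2.0])
        assert got == pytest.approx(-0.5 * np.log(2 * np.pi), rel=1e-12)

    def test_matches_dense_oracle(self, rng):
        for n in (3, 7, 20):
            x = np.sort(rng.uniform(0, 10, n))
            y = rng.normal(0.5, 1.0, n)
            assert log_marginal_likelihood(HP, x, y) == pytest.approx(
                oracle_lml(HP, x, y), rel=1e-10)

    def test_duplicated_point_agrees_with_oracle(self, rng):
        x = np.array([0.0, 1.0, 2.5, 2.5])
        y = np.array([0.1, 0.4, 0.3, 0.35])
        assert log_marginal_likelihood(HP, x, y) == pytest.approx(
            oracle_lml(HP, x, y), rel=1e-10)
        # duplicating a point (with noise) cannot inflate the per-point
        # average evidence beyond tolerance
        per_point_4 = log_marginal_likelihood(HP, x, y) / 4
        x3, y3 = x[:3], y[:3]
        per_point_3 = log_marginal_likelihood(HP, x3, y3) / 3
        assert per_point_4 <= per_point_3 + 0.5


# ----------------------------------------------------------------- predict

class TestPredict:
    def test_noiseless_interpolation(self):
        hp = GPHyperparams(1.0, 2.0, 0.0)
        x = np.array([0.0, 1.0, 3.0, 4.5])
        y = np.array([0.2, -0.3, 0.8, 0.1])
        model = condition(hp, x, y)
        pred = predict(model, x)
        np.testing.assert_allclose(pred.mean, y, atol=1e-8)
        np.testing.assert_allclose(pred.variance, 0.0, atol=1e-6)

    def test_prior_reversion_far_from_data(self):
        hp = GPHyperparams(1.7, 1.0, 0.05, constant_mean=0.9)
        model = condition(hp, [0.0, 1.0], [2.0, 1.5])
        pred = predict(model, [1000.0])
        assert pred.mean[0] == pytest.approx(0.9, abs=1e-8)
        assert pred.variance[0] == pytest.approx(1.7, abs=1e-8)

    def test_matches_dense_oracle(self, rng):
        x = np.array([0.0, 0.7, 1.9, 3.2])
        y = rng.normal(0.5, 1.0, 4)
        xs = np.array([-1.0, 0.35, 2.0, 5.0])
        model = condition(HP, x, y)
        pred = predict(model, xs)
        mu, var = oracle_predict(HP, x, y, xs)
        np.testing.assert_allclose(pred.mean, mu, rtol=1e-10)
        np.testing.assert_allclose(pred.variance, var, rtol=1e-8, atol=1e-12)

    def test_latent_variance_bounded_by_signal_variance(self, rng):
        x = rng.uniform(0, 10, 8)
        model = condition(HP, x, rng.normal(size=8))
        v = predict(model, np.linspace(-5, 15, 50)).variance
        assert (v >= -1e-12).all() and (v <= HP.signal_variance + 1e-9).all()

    def test_observation_bands_wider_than_latent(self, rng):
        x = rng.uniform(0, 10, 6)
        model = condition(HP, x, rng.normal(size=6))
        pred = predict(model, [5.0])
        half = (pred.ci95_high[0] - pred.ci95_low[0]) / 2
        assert half == pytest.approx(
            1.96 * np.sqrt(pred.variance[0] + HP.noise_variance), rel=1e-12)

    def test_adding_data_never_increases_latent_variance(self, rng):
        x = np.array([0.0, 2.0, 5.0])
        y = rng.normal(size=3)
        grid = np.linspace(-2, 8, 40)
        v_before = predict(condition(HP, x, y), grid).variance
        x2 = np.append(x, 3.3)
        y2 = np.append(y, 0.1)
        v_after = predict(condition(HP, x2, y2), grid).variance
        assert (v_after <= v_before + 1e-9).all()


# ---------------------------------------------------------------- fit/eval

class TestFit:
    def test_constant_outputs_degenerate(self):
        model = fit(np.arange(10.0), np.full(10, 4.2))
        pred = predict(model, [3.5, 100.0])
        np.testing.assert_allclose(pred.mean, 4.2, atol=1e-9)
        assert model.hyperparams.signal_variance <= 1e-9

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            fit([1.0, 2.0, np.inf], [0.0, 1.0, 2.0])

    def test_recovers_known_hyperparameters_single_seed(self):
        truth = GPHyperparams(1.0, 3.0, 0.01)
        rng = np.random.default_rng(5)
        x = np.arange(200.0)
        K = kernel_matrix(x, x, truth) + truth.noise_variance * np.eye(200)
        y = np.linalg.cholesky(K) @ rng.standard_normal(200)
        model = fit(x, y, OptimizerSettings(n_restarts=4, seed=0, maxiter=150))
        hp = model.hyperparams
        assert 0.3 < hp.length_scale / 3.0 < 3.0
        assert 0.2 < hp.signal_variance < 5.0
        assert 0.003 < hp.noise_variance < 0.03

    def test_smooth_trend_interpolation_quality(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 80)
        y = np.sin(x) + rng.normal(0, 0.05, 80)
        model = fit(x, y, OptimizerSettings(n_restarts=4, seed=1))
        pred = predict(model, x)
        assert np.sqrt(np.mean((pred.mean - np.sin(x)) ** 2)) < 0.05


class TestEvaluate:
    def test_perfect_and_mean_predictors(self):
        hp = GPHyperparams(1.0, 1.0, 0.0)
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 0.5])
        rep = evaluate(condition(hp, x, y), x, y)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        assert rep.rmse == pytest.approx(0.0, abs=1e-8)
        # a far-away query predicts the constant mean; centering y on its
        # mean makes that the mean predictor, hence R^2 = 0
        hp0 = GPHyperparams(1.0, 0.1, 0.0, constant_mean=y.mean())
        rep0 = evaluate(condition(hp0, x - 1000.0, y), x, y)
        assert rep0.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_matches_sum_of_squares_oracle(self, rng):
        x = rng.uniform(0, 5, 12)
        y = rng.normal(size=12)
        model = condition(HP, x[:8], y[:8])
        rep = evaluate(model, x[8:], y[8:])
        mu = predict(model, x[8:]).mean
        ss_res = np.sum((y[8:] - mu) ** 2)
        ss_tot = np.sum((y[8:] - y[8:].mean()) ** 2)
        assert rep.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        assert rep.rmse == pytest.approx(np.sqrt(ss_res / 4), rel=1e-12)

    def test_zero_variance_test_outputs_rejected(self):
        model = condition(HP, [0.0, 1.0], [0.5, 0.6])
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate(model, [2.0, 3.0], [1.0, 1.0])


class TestCrossValidate:
    def test_partition_covers_each_point_once(self):
        x = np.arange(10.0)
        y = np.sin(x)
        reports = crossvalidate(x, y, k_folds=5, settings=OptimizerSettings(
            n_restarts=2, maxiter=50))
        assert len(reports) == 5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(np.arange(3.0), np.arange(3.0), k_folds=5)

    def test_cv_consistent_with_holdout_on_smooth_trend(self):
        """On a high-SNR smooth rehabilitation-like trend, block CV and the
        chronological holdout measure the same predictive skill."""
        x = np.arange(150.0)
        f = 1.0 - 0.8 * (np.expm1(1.6 * x / 149) / np.expm1(1.6))
        y = f + np.random.default_rng(8).normal(0, 0.002, x.size)
        settings = OptimizerSettings(n_restarts=3, seed=2, maxiter=100)
        tx, ty, ex, ey = chronological_split(x, y, 0.8)
        hold = evaluate(fit(tx, ty, settings), ex, ey)
        scores = [r.r_squared for r in crossvalidate(x, y, 5, settings=settings)]
        assert all(s > 0.8 for s in scores)
        assert abs(np.mean(scores) - hold.r_squared) <= 0.1


def test_matches_reference_gp_implementation(rng):
    """Fixed-hyperparameter predictions agree with scikit-learn's GP."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel

    hp = GPHyperparams(1.3, 0.8, 0.05, constant_mean=0.0)
    x = np.sort(rng.uniform(0, 5, 15))
    y = rng.normal(size=15)
    xs = np.linspace(-1, 6, 30)
    ours = predict(condition(hp, x, y), xs)
    ref = GaussianProcessRegressor(
        kernel=ConstantKernel(hp.signal_variance, "fixed")
        * RBF(hp.length_scale, "fixed"),
        alpha=hp.noise_variance, optimizer=None).fit(x[:, None], y)
    mu, std = ref.predict(xs[:, None], return_std=True)
    np.testing.assert_allclose(ours.mean, mu, atol=1e-8)
    np.testing.assert_allclose(np.sqrt(ours.variance), std, atol=1e-6)
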