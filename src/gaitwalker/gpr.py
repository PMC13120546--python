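"""Gaussian Process Regression with an RBF kernel, written from first
principles.

Model: y(x) ~ GP(m, k) with constant mean m, squared-exponential covariance

    k(x, x') = sigma_f^2 * exp(-(x - x')^2 / (2 l^2))

and i.i.d. observation noise sigma_n^2. For training data (x, y) the
predictive distribution at x* is Gaussian with

    mu(x*)     = k*^T (K + sigma_n^2 I)^-1 (y - m) + m
    sigma^2(x*)= k** - k*^T (K + sigma_n^2 I)^-1 k*

Hyperparameters theta = (sigma_f^2, l, sigma_n^2) are chosen by maximizing
the log marginal likelihood

    log p(y | x, theta) = -1/2 (y-m)^T Ky^-1 (y-m) - 1/2 log|Ky| - n/2 log 2pi

with Ky = K + sigma_n^2 I, via multi-start L-BFGS in log-parameter space with
analytic gradients. All dense linear algebra goes through a Cholesky
factorization with escalating jitter. Intended for the walker's
force-trajectory series (n ~ 10^3), where dense solves are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPHyperparams",
    "GPModel",
    "PredictiveDistribution",
    "FitReport",
    "OptimizerSettings",
    "NumericalError",
    "rbf_kernel",
    "kernel_matrix",
    "condition",
    "log_marginal_likelihood",
    "fit",
    "predict",
    "evaluate",
    "crossvalidate",
    "chronological_split",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class NumericalError(RuntimeError):
    """Raised when the kernel matrix cannot be factorized even with jitter."""


@dataclass(frozen=True)
class GPHyperparams:
    signal_variance: float
    length_scale: float
    noise_variance: float
    constant_mean: float = 0.0

    def __post_init__(self):
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


def rbf_kernel(x, x_prime, hp: GPHyperparams):
    """Squared-exponential covariance between two inputs (vectorized)."""
    d = np.subtract(np.asarray(x, float), np.asarray(x_prime, float))
    out = hp.signal_variance * np.exp(-(d**2) / (2.0 * hp.length_scale**2))
    return float(out) if np.ndim(out) == 0 else out


def kernel_matrix(x1, x2, hp: GPHyperparams) -> np.ndarray:
    x1 = np.asarray(x1, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    d = x1[:, None] - x2[None, :]
    return hp.signal_variance * np.exp(-(d**2) / (2.0 * hp.length_scale**2))


def _chol(K: np.ndarray, hp=None) -> np.ndarray:
    scale = float(np.mean(np.diag(K))) or 1.0
    for j in _JITTERS:
        try:
            return linalg.cholesky(K + j * scale * np.eye(len(K)), lower=True)
        except linalg.LinAlgError:
            continue
    raise NumericalError(
        f"kernel matrix not positive definite even with jitter "
        f"{_JITTERS[-1]:g} (hyperparameters: {hp})")


@dataclass(frozen=True)
class GPModel:
    """A fitted GP: hyperparameters plus cached training factorization."""

    hyperparams: GPHyperparams
    train_x: np.ndarray
    train_y: np.ndarray
    chol_lower: np.ndarray = field(repr=False, default=None)
    alpha: np.ndarray = field(repr=False, default=None)  # Ky^-1 (y - m)


@dataclass(frozen=True)
class PredictiveDistribution:
    """Pointwise Gaussian predictions; ci95 bands are observation-level
    (they include the noise variance), matching bands drawn around noisy
    data."""

    mean: np.ndarray
    variance: np.ndarray  # latent-function variance
    ci95_low: np.ndarray
    ci95_high: np.ndarray


@dataclass(frozen=True)
class FitReport:
    r_squared: float
    rmse: float
    cv_fold_scores: tuple = ()
    split_fraction: float = 0.8
    hyperparams: GPHyperparams = None


@dataclass(frozen=True)
class OptimizerSettings:
    n_restarts: int = 8
    seed: int = 0
    maxiter: int = 200
    # log-space bounds relative to data scale are set inside fit()


def condition(hp: GPHyperparams, x, y) -> GPModel:
    """Condition a GP with *fixed* hyperparameters on training data
    (no optimization); useful for oracles and what-if analyses."""
    return _build_model(hp, x, y)


def _build_model(hp: GPHyperparams, x, y) -> GPModel:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    Ky = kernel_matrix(x, x, hp) + hp.noise_variance * np.eye(x.size)
    L = _chol(Ky, hp)
    alpha = linalg.cho_solve((L, True), y - hp.constant_mean)
    return GPModel(hyperparams=hp, train_x=x, train_y=y, chol_lower=L, alpha=alpha)


def log_marginal_likelihood(hp: GPHyperparams, x, y) -> float:
    """Log evidence of y under the GP prior plus noise (y centered by the
    constant mean)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 1:
        raise ValueError("x and y must be non-empty and of equal length")
    yc = y - hp.constant_mean
    Ky = kernel_matrix(x, x, hp) + hp.noise_variance * np.eye(x.size)
    L = _chol(Ky, hp)
    alpha = linalg.cho_solve((L, True), yc)
    return float(-0.5 * yc @ alpha - np.sum(np.log(np.diag(L)))
                 - 0.5 * x.size * np.log(2.0 * np.pi))


def _nll_and_grad(log_theta, D2, yc, n):
    sf2, l, sn2 = np.exp(log_theta)
    Kf = sf2 * np.exp(-D2 / (2.0 * l**2))
    Ky = Kf + sn2 * np.eye(n)
    try:
        L = _chol(Ky)
    except NumericalError:
        return np.inf, np.zeros(3)
    alpha = linalg.cho_solve((L, True), yc)
    lml = -0.5 * yc @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    # dK/dlog(sf2) = Kf ; dK/dlog(l) = Kf * D2 / l^2 ; dK/dlog(sn2) = sn2 I
    g = np.array([
        0.5 * np.sum(W * Kf),
        0.5 * np.sum(W * (Kf * D2 / l**2)),
        0.5 * sn2 * np.trace(W),
    ])
    return -lml, -g


def fit(x, y, settings: OptimizerSettings = OptimizerSettings()) -> GPModel:
    """Maximize the marginal likelihood over log-hyperparameters.

    Multi-start L-BFGS-B with analytic gradients; starts are drawn
    log-uniformly within data-scaled ranges (signal variance around var(y),
    length scale between ~2% and 100% of the input span, noise between 1e-4
    and 0.5 of var(y)), plus one heuristic start. The constant mean is fixed
    at the training-output average.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("hyperparameter optimization requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    m = float(y.mean())
    vy = float(y.var())
    span = float(x.max() - x.min()) or 1.0
    if vy == 0.0:
        # Degenerate constant outputs: the evidence pushes the signal variance
        # to its floor; predictions equal the constant mean.
        hp = GPHyperparams(signal_variance=1e-12, length_scale=span,
                           noise_variance=1e-12, constant_mean=m)
        return _build_model(hp, x, y)

    yc = y - m
    D2 = (x[:, None] - x[None, :]) ** 2
    rng = np.random.default_rng(settings.seed)
    lo = np.log([1e-3 * vy, span / 200.0, 1e-6 * vy])
    hi = np.log([1e2 * vy, 2.0 * span, 2.0 * vy])
    starts = [np.log([vy, span / 10.0, 0.1 * vy])]
    for _ in range(max(settings.n_restarts - 1, 0)):
        starts.append(rng.uniform(np.log([0.01 * vy, span / 50.0, 1e-4 * vy]),
                                  np.log([10.0 * vy, span, 0.5 * vy])))
    best = None
    failures = []
    for s0 in starts:
        res = optimize.minimize(
            _nll_and_grad, s0, args=(D2, yc, x.size), jac=True,
            method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": settings.maxiter})
        if np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
        else:
            failures.append(res.message)
    if best is None:
        raise NumericalError(f"all optimizer restarts failed: {failures}")
    sf2, l, sn2 = np.exp(best.x)
    hp = GPHyperparams(signal_variance=float(sf2), length_scale=float(l),
                       noise_variance=float(sn2), constant_mean=m)
    return _build_model(hp, x, y)


def predict(model: GPModel, x_star) -> PredictiveDistribution:
    """Predictive mean and variance at query points (vectorized).

    ``variance`` is the latent-function variance; the 95% intervals add the
    observation noise so the band envelops noisy data.
    """
    xs = np.atleast_1d(np.asarray(x_star, float)).ravel()
    hp = model.hyperparams
    Ks = kernel_matrix(xs, model.train_x, hp)  # (m, n)
    mean = Ks @ model.alpha + hp.constant_mean
    v = linalg.solve_triangular(model.chol_lower, Ks.T, lower=True)
    var = hp.signal_variance - np.einsum("ij,ij->j", v, v)
    var = np.maximum(var, 0.0)
    half = 1.96 * np.sqrt(var + hp.noise_variance)
    return PredictiveDistribution(mean=mean, variance=var,
                                  ci95_low=mean - half, ci95_high=mean + half)


def evaluate(model: GPModel, test_x, test_y, split_fraction: float = 0.8) -> FitReport:
    """Holdout metrics of the predictive mean: R^2 = 1 - SSres/SStot and
    RMSE."""
    ty = np.asarray(test_y, float).ravel()
    if ty.size == 0:
        raise ValueError("empty test set")
    if np.var(ty) == 0:
        raise ValueError("R^2 undefined: zero-variance test outputs")
    mu = predict(model, test_x).mean
    ss_res = float(np.sum((ty - mu) ** 2))
    ss_tot = float(np.sum((ty - ty.mean()) ** 2))
    return FitReport(r_squared=1.0 - ss_res / ss_tot,
                     rmse=float(np.sqrt(np.mean((ty - mu) ** 2))),
                     split_fraction=split_fraction,
                     hyperparams=model.hyperparams)


def chronological_split(x, y, train_fraction: float = 0.8):
    """Order by x and split into an early training block and late test tail.

    The device's use case is forecasting the remainder of a rehabilitation
    trajectory, so evaluation holds out the *future*.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    order = np.argsort(x, kind="stable")
    n_train = int(round(train_fraction * x.size))
    n_train = min(max(n_train, 1), x.size - 1)
    tr, te = order[:n_train], order[n_train:]
    return x[tr], y[tr], x[te], y[te]


def crossvalidate(x, y, k_folds: int = 5, seed: int = 0,
                  settings: OptimizerSettings = None) -> list:
    """Time-series-aware k-fold CV with contiguous blocks over sorted inputs.

    Each fold is a contiguous block of the x-ordered series; the model is
    refitted on the remaining blocks and scored on the held-out block.
    Returns one FitReport per fold.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} samples, got {x.size}")
    if settings is None:
        settings = OptimizerSettings(n_restarts=4, seed=seed)
    order = np.argsort(x, kind="stable")
    blocks = np.array_split(order, k_folds)
    reports = []
    for b in blocks:
        mask = np.ones(x.size, dtype=bool)
        mask[b] = False
        model = fit(x[mask], y[mask], settings)
        reports.append(evaluate(model, x[b], y[b],
                                split_fraction=1.0 - 1.0 / k_folds))
    return reports
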