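"""Regression backends: a feed-forward tanh ANN and Matérn-3/2 ARD GPR.

Both backends sit behind one train/predict contract (`TrainedSurrogate`).
The ANN is a plain numpy multilayer perceptron trained full-batch with Adam
on the mean-squared error; the GPR maximizes the marginal likelihood of a
constant × Matérn-3/2 kernel whose anisotropic distance divides squared
coordinate differences by the per-dimension lengthscale (an exponent flag
switches to the conventional squared-lengthscale form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .features import ColumnScaler, FeatureMatrix

__all__ = [
    "AnnConfig",
    "GprConfig",
    "TrainedSurrogate",
    "matern32_kernel",
    "fit_ann",
    "fit_gpr",
    "gpr_predict",
    "predict",
    "DivergenceError",
]

SQRT3 = np.sqrt(3.0)


class DivergenceError(RuntimeError):
    """ANN training loss became non-finite."""


# --------------------------------------------------------------------------- #
# configs
# --------------------------------------------------------------------------- #


@dataclass
class AnnConfig:
    hidden_layers: int = 2
    neurons_per_layer: int = 18
    activation: str = "tanh"
    epochs: int = 2048
    learning_rate: float = 0.02
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    # optional per-epoch Gaussian jitter on the z-scored inputs; acts as a
    # Tikhonov-style regularizer discouraging spurious feature dependence
    input_noise: float = 0.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation != "tanh":
            raise ValueError("only tanh activation is supported")

    @classmethod
    def deep_experimental(cls, **overrides) -> "AnnConfig":
        """Deeper net used for experimental-style (noisier) targets."""
        params = dict(hidden_layers=3, neurons_per_layer=90)
        params.update(overrides)
        return cls(**params)


@dataclass
class GprConfig:
    kernel_constant_init: float = 1.0
    lengthscales_init: np.ndarray | None = None
    noise_variance: float | None = None  # None: optimized (floored at jitter)
    max_train_points: int = 2000
    optimizer_restarts: int = 2
    seed: int = 0
    ard_exponent: int = 1  # 1: squared diff / l (as-printed); 2: conventional / l²

    def __post_init__(self):
        if self.max_train_points < 1:
            raise ValueError("max_train_points must be >= 1")
        if self.noise_variance is not None and self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.ard_exponent not in (1, 2):
            raise ValueError("ard_exponent must be 1 or 2")


@dataclass
class TrainedSurrogate:
    """A fitted map from named feature columns to named targets."""

    backend: str  # {"ann", "gpr"}
    input_columns: list[str]
    output_names: list[str]
    params: dict
    input_scaler: ColumnScaler
    target_scaler: ColumnScaler
    config: object = None
    seed: int = 0
    final_loss: float | None = None

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            if X.columns != self.input_columns:
                raise ValueError(
                    f"feature columns {X.columns} do not match training columns {self.input_columns}"
                )
            return X.X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.input_columns):
            raise ValueError(
                f"expected {len(self.input_columns)} feature columns, got shape {X.shape}"
            )
        return X

    def predict(self, X):
        return predict(self, X)


# --------------------------------------------------------------------------- #
# ANN backend
# --------------------------------------------------------------------------- #


def _init_mlp(rng: np.random.Generator, sizes: Sequence[int]):
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        weights.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
        biases.append(np.zeros(n_out))
    return weights, biases


def _mlp_forward(Xs, weights, biases):
    activations = [Xs]
    a = Xs
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ W + b)
        activations.append(a)
    out = a @ weights[-1] + biases[-1]
    return out, activations


def fit_ann(X, y, config: AnnConfig | None = None, input_columns=None, output_names=None) -> TrainedSurrogate:
    """Train the tanh MLP full-batch with Adam on the MSE loss.

    Inputs and targets are z-scored internally (statistics stored on the
    surrogate and reused at prediction time). Deterministic for a fixed seed.
    """
    config = config or AnnConfig()
    if isinstance(X, FeatureMatrix):
        input_columns = X.columns
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    n, d = X.shape
    n_out = y.shape[1]
    input_columns = list(input_columns) if input_columns is not None else [f"x{i}" for i in range(d)]
    output_names = list(output_names) if output_names is not None else [f"y{i}" for i in range(n_out)]

    in_scaler = ColumnScaler("zscore").fit(X)
    out_scaler = ColumnScaler("zscore").fit(y)
    Xs = in_scaler.transform(X)
    ys = out_scaler.transform(y)

    rng = np.random.default_rng(config.seed)
    sizes = [d] + [config.neurons_per_layer] * config.hidden_layers + [n_out]
    weights, biases = _init_mlp(rng, sizes)

    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    lr, b1, b2, eps = config.learning_rate, config.beta1, config.beta2, config.eps

    loss = np.inf
    for epoch in range(1, config.epochs + 1):
        X_in = Xs
        if config.input_noise > 0:
            X_in = Xs + config.input_noise * rng.standard_normal(Xs.shape)
        out, acts = _mlp_forward(X_in, weights, biases)
        resid = out - ys
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise DivergenceError(
                f"loss became non-finite at epoch {epoch}; try a smaller learning rate"
            )
        # backprop (loss = mean over all entries; constant factor 2/(n·n_out))
        grad_out = (2.0 / resid.size) * resid
        gw = [None] * len(weights)
        gb = [None] * len(biases)
        delta = grad_out
        for layer in range(len(weights) - 1, -1, -1):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
        t1 = 1.0 - b1**epoch
        t2 = 1.0 - b2**epoch
        for i in range(len(weights)):
            m_w[i] = b1 * m_w[i] + (1 - b1) * gw[i]
            v_w[i] = b2 * v_w[i] + (1 - b2) * gw[i] ** 2
            weights[i] -= lr * (m_w[i] / t1) / (np.sqrt(v_w[i] / t2) + eps)
            m_b[i] = b1 * m_b[i] + (1 - b1) * gb[i]
            v_b[i] = b2 * v_b[i] + (1 - b2) * gb[i] ** 2
            biases[i] -= lr * (m_b[i] / t1) / (np.sqrt(v_b[i] / t2) + eps)

    return TrainedSurrogate(
        backend="ann",
        input_columns=input_columns,
        output_names=output_names,
        params={"weights": weights, "biases": biases},
        input_scaler=in_scaler,
        target_scaler=out_scaler,
        config=config,
        seed=config.seed,
        final_loss=loss,
    )


def _ann_predict(model: TrainedSurrogate, X: np.ndarray) -> np.ndarray:
    Xs = model.input_scaler.transform(X)
    out, _ = _mlp_forward(Xs, model.params["weights"], model.params["biases"])
    return model.target_scaler.inverse_transform(out)


# --------------------------------------------------------------------------- #
# GPR backend
# --------------------------------------------------------------------------- #


def _ard_sq_dist(X1, X2, lengthscales, exponent):
    l = np.asarray(lengthscales, dtype=float)
    if np.any(l <= 0):
        raise ValueError("lengthscales must be positive")
    denom = l if exponent == 1 else l**2
    A = X1 / np.sqrt(denom)
    B = X2 / np.sqrt(denom)
    d2 = np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2.0 * A @ B.T
    return np.maximum(d2, 0.0)


def matern32_kernel(x_i, x_j, c: float, lengthscales, ard_exponent: int = 1):
    """k = c (1 + √3 d) exp(−√3 d), d² = Σ Δ²/l (or Δ²/l² for exponent 2).

    Accepts single vectors or 2-D stacks of row vectors; returns the full
    cross-covariance in the latter case.
    """
    x_i = np.atleast_2d(np.asarray(x_i, dtype=float))
    x_j = np.atleast_2d(np.asarray(x_j, dtype=float))
    if x_i.shape[1] != x_j.shape[1]:
        raise ValueError("feature dimensions differ")
    d = np.sqrt(_ard_sq_dist(x_i, x_j, lengthscales, ard_exponent))
    K = c * (1.0 + SQRT3 * d) * np.exp(-SQRT3 * d)
    if K.shape == (1, 1):
        return float(K[0, 0])
    return K


def _nll_and_grad(log_theta, Xs, ys, exponent, fixed_noise):
    """Negative log marginal likelihood and gradient in log-parameters.

    log_theta = [log c, log l_1..log l_d, (log σ²)].
    """
    n, d = Xs.shape
    c = np.exp(log_theta[0])
    l = np.exp(log_theta[1 : 1 + d])
    sigma2 = fixed_noise if fixed_noise is not None else np.exp(log_theta[1 + d])

    d2 = _ard_sq_dist(Xs, Xs, l, exponent)
    dist = np.sqrt(d2)
    E = np.exp(-SQRT3 * dist)
    K = c * (1.0 + SQRT3 * dist) * E
    Ky = K + (sigma2 + 1e-10) * np.eye(n)
    try:
        L = cholesky(Ky, lower=True)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(log_theta)
    alpha = cho_solve((L, True), ys)
    nll = 0.5 * float(ys @ alpha) + float(np.sum(np.log(np.diag(L)))) + 0.5 * n * np.log(2 * np.pi)

    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # dnll/dK = -0.5 W

    grad = np.zeros_like(log_theta)
    # d/d log c: dK/dlog c = K (noise excluded)
    grad[0] = -0.5 * float(np.sum(W * K))
    # d/d log l_k: dK/dd = -3 c d E; dd/dl_k = -(e/2) Δ²_k / (l_k^{e+1} d)
    dK_dd = -3.0 * c * dist * E
    e = exponent
    for k in range(d):
        diff2 = (Xs[:, k][:, None] - Xs[:, k][None, :]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            dd_dlk = np.where(dist > 0, -(e / 2.0) * diff2 / (l[k] ** (e + 1) * dist), 0.0)
        dK_dlk = dK_dd * dd_dlk
        grad[1 + k] = -0.5 * float(np.sum(W * dK_dlk)) * l[k]
    if fixed_noise is None:
        grad[1 + d] = -0.5 * float(np.trace(W)) * sigma2
    return nll, grad


def fit_gpr(X, y, config: GprConfig | None = None, input_columns=None, output_names=None) -> TrainedSurrogate:
    """Fit a single-output GP by maximizing the marginal likelihood.

    Hyperparameters (constant, ARD lengthscales, and the noise variance if
    not fixed) are optimized in log space by L-BFGS-B with multi-restarts;
    the best restart is kept. Training rows beyond ``max_train_points`` are
    thinned by uniform stride.
    """
    config = config or GprConfig()
    if isinstance(X, FeatureMatrix):
        input_columns = X.columns
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    n, d = X.shape
    input_columns = list(input_columns) if input_columns is not None else [f"x{i}" for i in range(d)]
    output_names = list(output_names) if output_names is not None else ["y"]

    if n > config.max_train_points:
        stride = int(np.ceil(n / config.max_train_points))
        keep = np.arange(0, n, stride)
        X, y = X[keep], y[keep]
        n = X.shape[0]

    in_scaler = ColumnScaler("zscore").fit(X)
    Xs = in_scaler.transform(X)
    # centered targets: zero prior mean
    out_scaler = ColumnScaler("zscore")
    out_scaler.shift = np.array([y.mean()])
    out_scaler.scale = np.array([1.0])
    ys = y - y.mean()

    rng = np.random.default_rng(config.seed)
    l0 = (
        np.asarray(config.lengthscales_init, dtype=float)
        if config.lengthscales_init is not None
        else np.ones(d)
    )
    c0 = max(config.kernel_constant_init, 1e-12)
    var_y = max(float(np.var(ys)), 1e-12)
    fixed_noise = config.noise_variance

    starts = [np.concatenate([[np.log(max(var_y, c0))], np.log(l0)])]
    for _ in range(max(config.optimizer_restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [[np.log(var_y) + rng.normal(0, 1)], np.log(l0) + rng.normal(0, 1, size=d)]
            )
        )
    if fixed_noise is None:
        starts = [np.concatenate([s, [np.log(max(var_y * 1e-3, 1e-8))]]) for s in starts]

    # bounds keep the kernel away from the degenerate constant-kernel optimum
    # (inputs are z-scored, so these are generous ranges)
    bounds = [(np.log(1e-6), np.log(1e6))] + [(np.log(1e-2), np.log(1e3))] * d
    if fixed_noise is None:
        bounds.append((np.log(1e-8), np.log(1e2)))

    best = None
    for s in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds]),
            args=(Xs, ys, config.ard_exponent, fixed_noise),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    c = float(np.exp(theta[0]))
    l = np.exp(theta[1 : 1 + d])
    sigma2 = fixed_noise if fixed_noise is not None else float(np.exp(theta[1 + d]))

    # precompute the predictive solve with jitter escalation
    K = matern32_kernel(Xs, Xs, c, l, config.ard_exponent)
    jitter = 1e-10
    while True:
        try:
            L_chol = cholesky(K + (sigma2 + jitter) * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > 1e-2:
                raise RuntimeError(
                    f"covariance remains ill-conditioned at jitter {jitter:.1e}; "
                    "check for duplicate rows or degenerate features"
                )
    alpha = cho_solve((L_chol, True), ys)

    return TrainedSurrogate(
        backend="gpr",
        input_columns=input_columns,
        output_names=output_names,
        params={
            "X_train": Xs,
            "alpha": alpha,
            "L": L_chol,
            "constant": c,
            "lengthscales": l,
            "noise_variance": sigma2,
            "jitter": jitter,
            "ard_exponent": config.ard_exponent,
        },
        input_scaler=in_scaler,
        target_scaler=out_scaler,
        config=config,
        seed=config.seed,
        final_loss=float(best.fun),
    )


def gpr_predict(model: TrainedSurrogate, X_star):
    """Predictive mean and pointwise variance of a fitted GP."""
    if model.backend != "gpr":
        raise ValueError("gpr_predict requires a GPR surrogate")
    Xq = model._coerce(X_star)
    p = model.params
    Xs = model.input_scaler.transform(Xq)
    Kx = matern32_kernel(Xs, p["X_train"], p["constant"], p["lengthscales"], p["ard_exponent"])
    Kx = np.atleast_2d(Kx)
    mean = Kx @ p["alpha"] + model.target_scaler.shift[0]
    v = solve_triangular(p["L"], Kx.T, lower=True)
    var = np.maximum(p["constant"] - np.sum(v**2, axis=0), 0.0)
    return mean, var


def predict(model: TrainedSurrogate, X):
    """Backend-dispatching point prediction (GPR returns the mean)."""
    Xq = model._coerce(X)
    if model.backend == "ann":
        out = _ann_predict(model, Xq)
        return out[:, 0] if out.shape[1] == 1 else out
    mean, _ = gpr_predict(model, Xq)
    return mean
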