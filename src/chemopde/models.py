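"""Constructors for every data-driven model variant.

Each model is a target definition (which operator columns feed which
targets) wired to a surrogate backend:

* black box, both PDEs: 6 operator features → (b_t, c_t)
* black box, single PDE: 6 features → b_t, c dynamics supplied analytically
* gray box: 6 features → b_t − D_b Δb (the unknown chemotactic residual)
* parametric gray box: features + sensing bounds p → analytic residual(p),
  then the bounds are recovered by minimizing the residual-mismatch loss
* delay (partial information): b-history features → forward-Euler increment
* chemonutrient observer: b-history features (with the arctan observable
  replacing the current raw gradient) → c
* second-order-in-time: (b, ∇b·r̂, Δb, b_t) → b_tt for experimental-style
  data where only b is measured
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .features import (
    ColumnScaler,
    DelaySpec,
    FeatureTable,
    arctan_observable,
)
from .simulate import (
    RadialGrid,
    SimulationConfig,
    SpatioTemporalField,
    chemotactic_term_pointwise,
)
from .surrogates import AnnConfig, GprConfig, TrainedSurrogate, fit_ann, fit_gpr, predict

__all__ = [
    "ModelSpec",
    "SensingBounds",
    "LearnedPDEModel",
    "MODEL_SIGNATURES",
    "train_blackbox_full",
    "train_blackbox_single",
    "train_graybox",
    "make_parametric_dataset",
    "train_parametric_graybox",
    "estimate_sensing_bounds",
    "train_delay_model",
    "train_observer",
    "observer_predict",
    "train_second_order",
    "DEFAULT_TRAIN_WINDOW",
]

# training window used throughout: (t ∈ [200, 230] s, r ∈ [0, 250] µm)
DEFAULT_TRAIN_WINDOW = ((200.0, 230.0), (0.0, 250.0))

_BC_FEATURES = ["b", "grad_b", "lap_b", "c", "grad_c", "lap_c"]
_DELAY_FEATURES = ["b", "grad_b", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"]
_OBSERVER_FEATURES = ["b", "atan_gb", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"]
_SECOND_ORDER_FEATURES = ["b", "grad_b", "lap_b", "b_t"]

MODEL_SIGNATURES = {
    "blackbox_full": (_BC_FEATURES, ["b_t", "c_t"]),
    "blackbox_single": (_BC_FEATURES, ["b_t"]),
    "graybox": (_BC_FEATURES, ["chemo_residual"]),
    "parametric_graybox": (_BC_FEATURES + ["c_plus", "c_minus"], ["chemo_residual"]),
    "delay_blackbox": (_DELAY_FEATURES, ["euler_increment"]),
    "delay_graybox": (_DELAY_FEATURES, ["euler_increment_minus_diffusion"]),
    "observer": (_OBSERVER_FEATURES, ["c"]),
    "second_order": (_SECOND_ORDER_FEATURES, ["b_tt"]),
}


@dataclass(frozen=True)
class SensingBounds:
    c_plus: float
    c_minus: float

    def __post_init__(self):
        if not (self.c_plus > self.c_minus > 0):
            raise ValueError("require c_plus > c_minus > 0")


@dataclass
class ModelSpec:
    kind: str
    backend: str = "ann"
    known_constants: dict = field(default_factory=dict)
    delay: DelaySpec | None = None

    def __post_init__(self):
        if self.kind not in MODEL_SIGNATURES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.backend not in ("ann", "gpr"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.kind in ("graybox", "delay_graybox") and "D_b" not in self.known_constants:
            raise ValueError(f"{self.kind} requires known D_b")

    @property
    def feature_columns(self):
        return list(MODEL_SIGNATURES[self.kind][0])

    @property
    def target_names(self):
        return list(MODEL_SIGNATURES[self.kind][1])


@dataclass
class LearnedPDEModel:
    """A surrogate wired into a right-hand-side / stepper contract."""

    spec: ModelSpec
    surrogates: list[TrainedSurrogate]
    grid: RadialGrid
    report_dt: float
    train_window: tuple
    feature_low: np.ndarray
    feature_high: np.ndarray
    sim_config: SimulationConfig | None = None  # analytic c dynamics for single/gray

    @property
    def kind(self):
        return self.spec.kind

    def predict_targets(self, X: np.ndarray) -> np.ndarray:
        """Stacked target predictions, one column per target name."""
        X = np.asarray(X, dtype=float)
        cols = []
        for s in self.surrogates:
            o = predict(s, X)
            cols.append(o if o.ndim == 2 else o[:, None])
        return np.hstack(cols)

    def support_fraction(self, X: np.ndarray, margin: float = 0.25) -> float:
        """Fraction of rows inside the (margin-expanded) training feature box."""
        span = np.maximum(self.feature_high - self.feature_low, 1e-30)
        lo = self.feature_low - margin * span
        hi = self.feature_high + margin * span
        inside = np.all((X >= lo) & (X <= hi), axis=1)
        return float(np.mean(inside))


# --------------------------------------------------------------------------- #
# shared plumbing
# --------------------------------------------------------------------------- #


def _fit_backend(spec, X, y, ann_config, gpr_config, seed):
    """One multi-output ANN, or one single-output GP per target."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if spec.backend == "ann":
        cfg = ann_config or AnnConfig(seed=seed)
        return [
            fit_ann(X, y, cfg, input_columns=spec.feature_columns, output_names=spec.target_names)
        ]
    cfg = gpr_config or GprConfig(seed=seed)
    return [
        fit_gpr(X, y[:, j], cfg, input_columns=spec.feature_columns, output_names=[name])
        for j, name in enumerate(spec.target_names)
    ]


def _check_samples(n, min_samples):
    if n < min_samples:
        raise ValueError(f"only {n} training samples after subsampling (need >= {min_samples})")


def _model_from_table(
    spec, table, window, stride, targets, ann_config, gpr_config, seed, min_samples, sim_config
):
    t_idx, r_idx = table.sample_indices(window, stride)
    X = table.extract(spec.feature_columns, t_idx, r_idx)
    _check_samples(X.shape[0], min_samples)
    surrogates = _fit_backend(spec, X, targets(t_idx, r_idx), ann_config, gpr_config, seed)
    return LearnedPDEModel(
        spec=spec,
        surrogates=surrogates,
        grid=table.grid,
        report_dt=table.report_dt,
        train_window=window,
        feature_low=X.min(axis=0),
        feature_high=X.max(axis=0),
        sim_config=sim_config,
    )


# --------------------------------------------------------------------------- #
# continuous-time models
# --------------------------------------------------------------------------- #


def train_blackbox_full(
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    backend: str = "ann",
    stride=(2, 3),
    ann_config: AnnConfig | None = None,
    gpr_config: GprConfig | None = None,
    seed: int = 0,
    min_samples: int = 100,
) -> LearnedPDEModel:
    """Learn both right-hand sides: 6 operator features → (b_t, c_t)."""
    spec = ModelSpec(kind="blackbox_full", backend=backend)
    table = FeatureTable([b, c])
    targets = lambda ti, ri: table.extract(["b_t", "c_t"], ti, ri)
    return _model_from_table(
        spec, table, window, stride, targets, ann_config, gpr_config, seed, min_samples, None
    )


def train_blackbox_single(
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    backend: str = "ann",
    stride=(2, 3),
    ann_config: AnnConfig | None = None,
    gpr_config: GprConfig | None = None,
    seed: int = 0,
    min_samples: int = 100,
    sim_config: SimulationConfig | None = None,
) -> LearnedPDEModel:
    """Learn only b_t; the c equation is supplied analytically at rollout."""
    spec = ModelSpec(kind="blackbox_single", backend=backend)
    table = FeatureTable([b, c])
    targets = lambda ti, ri: table.extract(["b_t"], ti, ri)
    return _model_from_table(
        spec, table, window, stride, targets, ann_config, gpr_config, seed, min_samples, sim_config
    )


def train_graybox(
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    D_b: float = 2.325,
    backend: str = "ann",
    stride=(2, 3),
    ann_config: AnnConfig | None = None,
    gpr_config: GprConfig | None = None,
    seed: int = 0,
    min_samples: int = 100,
    sim_config: SimulationConfig | None = None,
) -> LearnedPDEModel:
    """Learn the residual b_t − D_b Δb (chemotactic + growth term) only."""
    spec = ModelSpec(kind="graybox", backend=backend, known_constants={"D_b": D_b})
    table = FeatureTable([b, c])

    def targets(ti, ri):
        cols = table.extract(["b_t", "lap_b"], ti, ri)
        return cols[:, 0] - D_b * cols[:, 1]

    return _model_from_table(
        spec, table, window, stride, targets, ann_config, gpr_config, seed, min_samples, sim_config
    )


# --------------------------------------------------------------------------- #
# parametric gray box and sensing-bound estimation
# --------------------------------------------------------------------------- #


def make_parametric_dataset(
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    n_samples: int = 10_000,
    seed: int = 0,
    rel_perturb: float = 0.10,
    chi0: float = 17.9,
    p_true: tuple[float, float] = (30.0, 1.0),
    p_factor_range: tuple[float, float] = (0.5, 2.0),
):
    """Artificial (features, p) → chemotactic-term dataset of given size.

    Rows are simulation samples perturbed multiplicatively (uniform
    ±rel_perturb per entry) with sensing bounds drawn uniformly in
    ``p_factor_range`` × the true bounds; targets are evaluated with the
    analytic chemotactic term at each sampled p. Rows violating
    c_plus > c_minus are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    table = FeatureTable([b, c])
    t_idx, r_idx = table.sample_indices(window)
    base = table.extract(_BC_FEATURES, t_idx, r_idx)

    rows = rng.integers(0, base.shape[0], size=n_samples)
    X = base[rows] * (1.0 + rng.uniform(-rel_perturb, rel_perturb, size=(n_samples, base.shape[1])))
    X[:, 3] = np.maximum(X[:, 3], 0.0)  # perturbed c stays physical

    lo, hi = p_factor_range
    c_plus = p_true[0] * rng.uniform(lo, hi, size=n_samples)
    c_minus = p_true[1] * rng.uniform(lo, hi, size=n_samples)
    bad = c_plus <= c_minus
    while np.any(bad):
        c_plus[bad] = p_true[0] * rng.uniform(lo, hi, size=int(bad.sum()))
        c_minus[bad] = p_true[1] * rng.uniform(lo, hi, size=int(bad.sum()))
        bad = c_plus <= c_minus

    y = chemotactic_term_pointwise(
        X[:, 0], X[:, 1], X[:, 3], X[:, 4], X[:, 5], chi0, c_minus, c_plus
    )
    Xp = np.column_stack([X, c_plus, c_minus])
    return Xp, y


def train_parametric_graybox(
    dataset: tuple[np.ndarray, np.ndarray],
    backend: str = "ann",
    ann_config: AnnConfig | None = None,
    seed: int = 0,
) -> TrainedSurrogate:
    """Train g(features, p) on the perturbed dataset."""
    X, y = dataset
    X = np.asarray(X, dtype=float)
    if X.shape[1] != 8:
        raise ValueError("parametric dataset must have 8 columns (6 features + c_plus, c_minus)")
    for j, name in ((6, "c_plus"), (7, "c_minus")):
        if np.ptp(X[:, j]) < 1e-12:
            raise ValueError(f"parameter column {name} has no span; cannot identify p")
    if backend != "ann":
        raise ValueError("parametric gray box uses the ANN backend")
    cfg = ann_config or AnnConfig(seed=seed)
    return fit_ann(
        X,
        y,
        cfg,
        input_columns=MODEL_SIGNATURES["parametric_graybox"][0],
        output_names=["chemo_residual"],
    )


def estimate_sensing_bounds(
    surrogate: TrainedSurrogate,
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    D_b: float,
    window=DEFAULT_TRAIN_WINDOW,
    stride=(4, 3),
    p0: tuple[float, float] = (50.0, 5.0),
    n_starts: int = 5,
    seed: int = 0,
):
    """Recover (c_plus, c_minus) by minimizing ‖b_t − D_b Δb − g(·, p)‖².

    Quasi-Newton (BFGS) in log-parameters for positivity; multiple seeded
    starts around p0; the average over the starts is reported.
    """
    table = FeatureTable([b, c])
    t_idx, r_idx = table.sample_indices(window, stride)
    feats = table.extract(_BC_FEATURES, t_idx, r_idx)
    cols = table.extract(["b_t", "lap_b"], t_idx, r_idx)
    target = cols[:, 0] - D_b * cols[:, 1]
    scale = float(np.mean(target**2)) or 1.0

    def loss(z):
        cp, cm = np.exp(z)
        if cp <= cm:
            return 1e6 * (1.0 + cm - cp)
        X = np.column_stack([feats, np.full(len(feats), cp), np.full(len(feats), cm)])
        resid = target - predict(surrogate, X)
        return float(np.sum(resid**2)) / scale / len(feats)

    rng = np.random.default_rng(seed)
    solutions, details = [], []
    for k in range(n_starts):
        z0 = np.log(np.asarray(p0, dtype=float))
        if k > 0:
            z0 = z0 + rng.normal(0.0, 0.3, size=2)
        res = minimize(loss, z0, method="BFGS", options={"maxiter": 200})
        p_hat = np.exp(res.x)
        details.append(
            {
                "start": np.exp(z0).tolist(),
                "p": p_hat.tolist(),
                "loss": float(res.fun),
                "converged": bool(res.success),
            }
        )
        if not res.success:
            warnings.warn(f"BFGS start {k} did not fully converge; keeping best iterate")
        solutions.append(p_hat)
    mean_p = np.mean(solutions, axis=0)
    return SensingBounds(c_plus=float(mean_p[0]), c_minus=float(mean_p[1])), details


# --------------------------------------------------------------------------- #
# delay (partial-information) models
# --------------------------------------------------------------------------- #


def train_delay_model(
    b: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    delay: DelaySpec | None = None,
    variant: str = "black",
    D_b: float | None = None,
    backend: str = "ann",
    stride=(2, 3),
    ann_config: AnnConfig | None = None,
    gpr_config: GprConfig | None = None,
    seed: int = 0,
    min_samples: int = 100,
) -> LearnedPDEModel:
    """Discrete-time stepper from b-history only (no c measurements).

    Trains f such that b(t+Δt) = b(t) + Δt·f(features(t), features(t−Δt));
    the gray variant learns the residual after the analytic D_b Δb Euler
    contribution. The surrogate's target is the Δt-normalized increment.
    """
    if variant not in ("black", "gray"):
        raise ValueError("variant must be 'black' or 'gray'")
    if variant == "gray" and D_b is None:
        raise ValueError("gray delay variant requires D_b")
    delay = delay or DelaySpec(delta_t=b.report_dt)
    kind = "delay_blackbox" if variant == "black" else "delay_graybox"
    spec = ModelSpec(
        kind=kind, backend=backend, known_constants={} if D_b is None else {"D_b": D_b}, delay=delay
    )
    table = FeatureTable([b], delay=delay)
    s = table.lag_steps
    dt = s * table.report_dt

    t_idx, r_idx = table.sample_indices(window, stride)
    t_idx = t_idx[t_idx + s < table.times.size]  # need b(t_{k+1})
    if t_idx.size == 0:
        raise ValueError("window leaves no room for the lead target")
    X = table.extract(spec.feature_columns, t_idx, r_idx)
    _check_samples(X.shape[0], min_samples)
    b_now = table.arrays["b"][np.ix_(t_idx, r_idx)].ravel()
    b_next = table.arrays["b"][np.ix_(t_idx + s, r_idx)].ravel()
    y = (b_next - b_now) / dt
    if variant == "gray":
        y = y - D_b * table.arrays["lap_b"][np.ix_(t_idx, r_idx)].ravel()

    surrogates = _fit_backend(spec, X, y, ann_config, gpr_config, seed)
    return LearnedPDEModel(
        spec=spec,
        surrogates=surrogates,
        grid=b.grid,
        report_dt=dt,
        train_window=window,
        feature_low=X.min(axis=0),
        feature_high=X.max(axis=0),
    )


# --------------------------------------------------------------------------- #
# chemonutrient observer
# --------------------------------------------------------------------------- #


def train_observer(
    b: SpatioTemporalField,
    c: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    delay: DelaySpec | None = None,
    stride=(2, 3),
    use_arctan: bool = True,
    ann_config: AnnConfig | None = None,
    seed: int = 0,
) -> TrainedSurrogate:
    """Soft sensor for c(r, t) from local b-history features.

    The current raw gradient is replaced by the quadrant-aware arctan
    observable of the [−1,1]-scaled (b, ∇b·r̂) pair; the delayed features
    enter raw. ``use_arctan=False`` keeps the raw gradient instead (for
    ablation studies). The [−1,1] affine statistics are fitted on the whole
    training window and stored on the surrogate for reuse at prediction.
    """
    delay = delay or DelaySpec(delta_t=b.report_dt)
    table = FeatureTable([b], delay=delay)
    t_idx, r_idx = table.sample_indices(window, stride)
    raw = table.extract(
        ["b", "grad_b", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"], t_idx, r_idx
    )
    y = c.values[np.ix_(t_idx, r_idx)].ravel()

    if use_arctan:
        mm = ColumnScaler("maxabs").fit(raw[:, :2])  # (b, grad_b) → [−1, 1], sign kept
        scaled = mm.transform(raw[:, :2])
        obs = arctan_observable(scaled[:, 0], scaled[:, 1])
        X = np.column_stack([raw[:, 0], obs, raw[:, 2:]])
        columns = list(_OBSERVER_FEATURES)
    else:
        mm = None
        X = raw
        columns = ["b", "grad_b", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"]

    cfg = ann_config or AnnConfig(seed=seed)
    surrogate = fit_ann(X, y, cfg, input_columns=columns, output_names=["c"])
    surrogate.params["arctan_minmax"] = mm
    surrogate.params["delay"] = delay
    return surrogate


def observer_predict(
    surrogate: TrainedSurrogate,
    b: SpatioTemporalField,
    window=None,
    stride=(1, 1),
):
    """Apply a trained observer over a window; returns (c_hat, t_idx, r_idx)."""
    mm = surrogate.params.get("arctan_minmax")
    delay = surrogate.params.get("delay")
    if mm is None and "atan_gb" in surrogate.input_columns:
        raise ValueError("observer is missing its stored arctan scaling statistics")
    table = FeatureTable([b], delay=delay)
    t_idx, r_idx = table.sample_indices(window, stride)
    raw = table.extract(
        ["b", "grad_b", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"], t_idx, r_idx
    )
    if mm is not None:
        scaled = mm.transform(raw[:, :2])
        obs = arctan_observable(scaled[:, 0], scaled[:, 1])
        X = np.column_stack([raw[:, 0], obs, raw[:, 2:]])
    else:
        X = raw
    c_hat = predict(surrogate, X).reshape(t_idx.size, r_idx.size)
    return c_hat, t_idx, r_idx


# --------------------------------------------------------------------------- #
# second-order-in-time model (experimental-style, b only)
# --------------------------------------------------------------------------- #


def train_second_order(
    b: SpatioTemporalField,
    window=DEFAULT_TRAIN_WINDOW,
    stride=(2, 3),
    ann_config: AnnConfig | None = None,
    seed: int = 0,
    min_samples: int = 100,
) -> LearnedPDEModel:
    """b_tt = f(b, ∇b·r̂, Δb, b_t), rolled out as two first-order equations."""
    if b.times.size < 4:
        raise ValueError(
            "need >= 4 time points to estimate b_tt; interpolate in time first "
            "(preprocess.interpolate_time_rbf)"
        )
    spec = ModelSpec(kind="second_order", backend="ann")
    table = FeatureTable([b], with_second_time_derivative=True)
    cfg = ann_config or AnnConfig.deep_experimental(seed=seed)

    t_idx, r_idx = table.sample_indices(window, stride)
    # one-sided time stencils at the series ends are first-order; drop them
    interior = (t_idx > 0) & (t_idx < table.times.size - 1)
    t_idx = t_idx[interior]
    X = table.extract(spec.feature_columns, t_idx, r_idx)
    _check_samples(X.shape[0], min_samples)
    y = table.arrays["b_tt"][np.ix_(t_idx, r_idx)].ravel()
    surrogates = [fit_ann(X, y, cfg, input_columns=spec.feature_columns, output_names=["b_tt"])]
    return LearnedPDEModel(
        spec=spec,
        surrogates=surrogates,
        grid=b.grid,
        report_dt=b.report_dt,
        train_window=window,
        feature_low=X.min(axis=0),
        feature_high=X.max(axis=0),
    )
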