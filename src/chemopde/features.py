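"""Coordinate-invariant local operators and feature-matrix assembly.

Every learned model consumes rows of local operators — the field value, the
radial component of its gradient, and the Laplacian (cylindrical-radial
1/r ∂r(r ∂r u) or plain Cartesian u''), optionally with one delayed copy —
so that the learned law is independent of the coordinate system the data
came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Iterable, Sequence

import numpy as np

from .simulate import RadialGrid, SpatioTemporalField

__all__ = [
    "radial_gradient",
    "laplacian",
    "divergence_radial",
    "time_derivative",
    "arctan_observable",
    "DelaySpec",
    "ColumnScaler",
    "FeatureMatrix",
    "FeatureTable",
    "assemble_feature_matrix",
]


# --------------------------------------------------------------------------- #
# stencil operators (second-order central, one-sided at the outer edge)
# --------------------------------------------------------------------------- #


def radial_gradient(u, grid: RadialGrid):
    """∇u·r̂ on the grid. Zero at r = 0 by symmetry (cylindrical mode)."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != grid.n:
        raise ValueError(f"row length {u.shape[-1]} != grid size {grid.n}")
    if grid.n < 3:
        raise ValueError("need at least 3 grid points for second-order stencils")
    dr = grid.dr
    g = np.empty_like(u)
    g[..., 1:-1] = (u[..., 2:] - u[..., :-2]) / (2.0 * dr)
    g[..., -1] = (3.0 * u[..., -1] - 4.0 * u[..., -2] + u[..., -3]) / (2.0 * dr)
    if grid.coordinate_mode == "cylindrical-radial" and grid.starts_at_origin:
        g[..., 0] = 0.0  # symmetry at the axis
    else:
        g[..., 0] = (-3.0 * u[..., 0] + 4.0 * u[..., 1] - u[..., 2]) / (2.0 * dr)
    return g


def _second_derivative(u, dr):
    d2 = np.empty_like(u)
    d2[..., 1:-1] = (u[..., 2:] - 2.0 * u[..., 1:-1] + u[..., :-2]) / dr**2
    d2[..., 0] = (2.0 * u[..., 0] - 5.0 * u[..., 1] + 4.0 * u[..., 2] - u[..., 3]) / dr**2
    d2[..., -1] = (2.0 * u[..., -1] - 5.0 * u[..., -2] + 4.0 * u[..., -3] - u[..., -4]) / dr**2
    return d2


def laplacian(u, grid: RadialGrid):
    """Δu in the grid's coordinate mode.

    Cylindrical-radial: (1/r)∂r(r ∂r u) with the symmetry limit
    Δu|_{r=0} = 2 u''(0); Cartesian: plain u''.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != grid.n:
        raise ValueError(f"row length {u.shape[-1]} != grid size {grid.n}")
    if grid.n < 4:
        raise ValueError("need at least 4 grid points for second-order stencils")
    dr = grid.dr
    if grid.coordinate_mode == "cartesian-1d":
        return _second_derivative(u, dr)
    if grid.coordinate_mode != "cylindrical-radial":
        raise ValueError(f"unknown coordinate_mode {grid.coordinate_mode!r}")
    lap = np.empty_like(u)
    r = grid.r
    # conservative interior stencil: (r_{i+1/2} δ₊u − r_{i−1/2} δ₋u)/(r_i dr²)
    rp = (r[1:-1] + r[2:]) / 2.0
    rm = (r[:-2] + r[1:-1]) / 2.0
    lap[..., 1:-1] = (rp * (u[..., 2:] - u[..., 1:-1]) - rm * (u[..., 1:-1] - u[..., :-2])) / (
        r[1:-1] * dr**2
    )
    if grid.starts_at_origin:
        # origin: even symmetry gives u''(0) = 2(u₁−u₀)/dr², and Δu = 2u''(0)
        lap[..., 0] = 4.0 * (u[..., 1] - u[..., 0]) / dr**2
    else:
        lo_up = (-3.0 * u[..., 0] + 4.0 * u[..., 1] - u[..., 2]) / (2.0 * dr)
        lo_upp = (2.0 * u[..., 0] - 5.0 * u[..., 1] + 4.0 * u[..., 2] - u[..., 3]) / dr**2
        lap[..., 0] = lo_upp + lo_up / r[0]
    # outer edge: Δu = u'' + u'/r with one-sided stencils
    up = (3.0 * u[..., -1] - 4.0 * u[..., -2] + u[..., -3]) / (2.0 * dr)
    upp = (2.0 * u[..., -1] - 5.0 * u[..., -2] + 4.0 * u[..., -3] - u[..., -4]) / dr**2
    lap[..., -1] = upp + up / r[-1]
    return lap


def operators_no_flux(u, grid: RadialGrid):
    """(∇u·r̂, Δu) with zero-normal-gradient mirror ghosts at both ends.

    Used when evaluating learned right-hand sides during rollout, where the
    sub-domain boundary carries a no-flux condition instead of data beyond
    the edge.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != grid.n:
        raise ValueError("shape mismatch with grid")
    dr = grid.dr
    g = np.empty_like(u)
    g[..., 1:-1] = (u[..., 2:] - u[..., :-2]) / (2.0 * dr)
    g[..., 0] = 0.0
    g[..., -1] = 0.0
    lap = np.empty_like(u)
    if grid.coordinate_mode == "cylindrical-radial":
        r = grid.r
        rp = (r[1:-1] + r[2:]) / 2.0
        rm = (r[:-2] + r[1:-1]) / 2.0
        lap[..., 1:-1] = (
            rp * (u[..., 2:] - u[..., 1:-1]) - rm * (u[..., 1:-1] - u[..., :-2])
        ) / (r[1:-1] * dr**2)
        if grid.starts_at_origin:
            lap[..., 0] = 4.0 * (u[..., 1] - u[..., 0]) / dr**2
        else:
            lap[..., 0] = 2.0 * (u[..., 1] - u[..., 0]) / dr**2
        # mirror ghost: u' = 0 at R, so Δu = u'' = 2(u_{n−2} − u_{n−1})/dr²
        lap[..., -1] = 2.0 * (u[..., -2] - u[..., -1]) / dr**2
    else:
        lap[..., 1:-1] = (u[..., 2:] - 2.0 * u[..., 1:-1] + u[..., :-2]) / dr**2
        lap[..., 0] = 2.0 * (u[..., 1] - u[..., 0]) / dr**2
        lap[..., -1] = 2.0 * (u[..., -2] - u[..., -1]) / dr**2
    return g, lap


def divergence_radial(v, grid: RadialGrid):
    """Divergence of the radial vector field v r̂ in the grid's mode."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != grid.n:
        raise ValueError("shape mismatch with grid")
    dv = radial_gradient(v, grid)
    if grid.coordinate_mode == "cartesian-1d":
        return dv
    out = np.empty_like(v)
    r = grid.r
    out[..., 1:] = dv[..., 1:] + v[..., 1:] / r[1:]
    if grid.starts_at_origin:
        # v(0) = 0 by symmetry; the limit of v' + v/r at the origin is 2 v'(0)
        out[..., 0] = 2.0 * (v[..., 1] - v[..., 0]) / grid.dr
    else:
        out[..., 0] = dv[..., 0] + v[..., 0] / r[0]
    return out


def time_derivative(field: SpatioTemporalField, order: int = 1) -> SpatioTemporalField:
    """∂u/∂t (order 1) or ∂²u/∂t² (order 2) by central differences in time."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t = field.times
    if t.size < (3 if order == 1 else 4):
        raise ValueError("not enough time points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError(
            "times are not uniformly spaced; resample first (preprocess.interpolate_time_rbf)"
        )
    u = field.values
    h = dt[0]
    out = np.empty_like(u)
    if order == 1:
        out[1:-1] = (u[2:] - u[:-2]) / (2.0 * h)
        out[0] = (-3.0 * u[0] + 4.0 * u[1] - u[2]) / (2.0 * h)
        out[-1] = (3.0 * u[-1] - 4.0 * u[-2] + u[-3]) / (2.0 * h)
        name = f"{field.name}_t"
    else:
        out[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / h**2
        out[0] = (2.0 * u[0] - 5.0 * u[1] + 4.0 * u[2] - u[3]) / h**2
        out[-1] = (2.0 * u[-1] - 5.0 * u[-2] + 4.0 * u[-3] - u[-4]) / h**2
        name = f"{field.name}_tt"
    return SpatioTemporalField(out, t, field.grid, name=name, units=f"{field.units}/s^{order}")


def arctan_observable(b_scaled, grad_b_scaled):
    """Quadrant-aware arctan(ḡ/b̄) of the two [−1,1]-scaled inputs.

    Separates the flat region ahead of a traveling band from the flat region
    behind it by sign; the (0, 0) singular point maps to 0.
    """
    b_scaled = np.asarray(b_scaled, dtype=float)
    grad_b_scaled = np.asarray(grad_b_scaled, dtype=float)
    return np.arctan2(grad_b_scaled, b_scaled)


# --------------------------------------------------------------------------- #
# scaling
# --------------------------------------------------------------------------- #


@dataclass
class ColumnScaler:
    """Per-column affine scaling with stored statistics.

    kind 'zscore': (x − mean)/std;  kind 'minmax': affine map onto [−1, 1];
    kind 'maxabs': x/max|x| — the sign-preserving affine map into [−1, 1]
    (used for the arctan observable inputs, where the sign carries meaning).
    Statistics are fitted once on training data and reused verbatim.
    """

    kind: str = "zscore"
    shift: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        if self.kind == "zscore":
            self.shift = X.mean(axis=0)
            std = X.std(axis=0)
            self.scale = np.where(std > 0, std, 1.0)
        elif self.kind == "minmax":
            lo, hi = X.min(axis=0), X.max(axis=0)
            span = hi - lo
            self.scale = np.where(span > 0, span / 2.0, 1.0)
            self.shift = (hi + lo) / 2.0
        elif self.kind == "maxabs":
            amax = np.abs(X).max(axis=0)
            self.scale = np.where(amax > 0, amax, 1.0)
            self.shift = np.zeros(X.shape[1] if X.ndim > 1 else 1)
        else:
            raise ValueError(f"unknown scaling kind {self.kind!r}")
        return self

    def transform(self, X):
        if self.shift is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.shift) / self.scale

    def inverse_transform(self, Z):
        if self.shift is None:
            raise RuntimeError("scaler not fitted")
        return np.asarray(Z, dtype=float) * self.scale + self.shift


# --------------------------------------------------------------------------- #
# feature assembly
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DelaySpec:
    """Single fixed delay between consecutive feature snapshots."""

    delta_t: float
    n_delays: int = 1

    def steps(self, report_dt: float) -> int:
        k = self.delta_t / report_dt
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError(
                f"delay {self.delta_t} is not a positive integer multiple of the report interval {report_dt}"
            )
        return int(round(k))


@dataclass
class FeatureMatrix:
    """Rows of named local-operator features with provenance and scaling."""

    X: np.ndarray
    columns: list[str]
    t_index: np.ndarray  # time index of each row in the source fields
    r_index: np.ndarray  # space index of each row
    scaler: ColumnScaler | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X must be 2-D with one column per name")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN/Inf")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def scaled(self) -> np.ndarray:
        if self.scaler is None:
            return self.X
        return self.scaler.transform(self.X)


class FeatureTable:
    """All operator fields derived from a set of spatiotemporal fields.

    Columns: for each input field ``u`` the entries ``u``, ``grad_u``,
    ``lap_u``; time derivatives ``u_t`` (and ``u_tt`` on request); delayed
    copies ``<col>_lag1``… when a delay is given.
    """

    def __init__(
        self,
        fields: Sequence[SpatioTemporalField],
        delay: DelaySpec | None = None,
        with_second_time_derivative: bool = False,
    ):
        if not fields:
            raise ValueError("no fields given")
        self.grid = fields[0].grid
        self.times = fields[0].times
        for f in fields[1:]:
            if f.grid.n != self.grid.n or f.times.size != self.times.size:
                raise ValueError("all fields must share grid and times")
        self.delay = delay
        self.report_dt = float(self.times[1] - self.times[0])
        self.lag_steps = delay.steps(self.report_dt) if delay is not None else 0
        self.arrays: dict[str, np.ndarray] = {}
        for f in fields:
            name = f.name or "u"
            self.arrays[name] = f.values
            self.arrays[f"grad_{name}"] = radial_gradient(f.values, self.grid)
            self.arrays[f"lap_{name}"] = laplacian(f.values, self.grid)
            self.arrays[f"{name}_t"] = time_derivative(f, order=1).values
            if with_second_time_derivative:
                self.arrays[f"{name}_tt"] = time_derivative(f, order=2).values
        if delay is not None:
            base = list(self.arrays.keys())
            for lag in range(1, delay.n_delays + 1):
                s = lag * self.lag_steps
                for col in base:
                    lagged = np.full_like(self.arrays[col], np.nan)
                    lagged[s:] = self.arrays[col][:-s] if s else self.arrays[col]
                    self.arrays[f"{col}_lag{lag}"] = lagged

    def sample_indices(self, window=None, stride=(1, 1)):
        """(t_idx, r_idx) covering the window at the given (t, r) strides."""
        t_range, r_range = (None, None) if window is None else window
        tol = 1e-9
        t_mask = np.ones(self.times.size, dtype=bool)
        if t_range is not None:
            t_mask &= (self.times >= t_range[0] - tol) & (self.times <= t_range[1] + tol)
        # rows needing lagged columns must leave room for the delay
        if self.lag_steps:
            t_mask[: self.lag_steps * (self.delay.n_delays if self.delay else 1)] = False
        r = self.grid.r
        r_mask = np.ones(r.size, dtype=bool)
        if r_range is not None:
            r_mask &= (r >= r_range[0] - tol) & (r <= r_range[1] + tol)
        t_idx = np.nonzero(t_mask)[0][:: stride[0]]
        r_idx = np.nonzero(r_mask)[0][:: stride[1]]
        if t_idx.size == 0 or r_idx.size == 0:
            raise ValueError("window selects no samples")
        return t_idx, r_idx

    def extract(self, columns: Iterable[str], t_idx, r_idx) -> np.ndarray:
        """Stack the named columns at the (t × r) index grid into rows."""
        cols = []
        for name in columns:
            if name not in self.arrays:
                raise KeyError(f"unknown feature column {name!r}; have {sorted(self.arrays)}")
            cols.append(self.arrays[name][np.ix_(t_idx, r_idx)].ravel())
        return np.column_stack(cols)

    def matrix(
        self,
        columns: Sequence[str],
        window=None,
        stride=(1, 1),
        scaling: str | None = "zscore",
    ) -> FeatureMatrix:
        t_idx, r_idx = self.sample_indices(window, stride)
        X = self.extract(columns, t_idx, r_idx)
        tt, rr = np.meshgrid(t_idx, r_idx, indexing="ij")
        scaler = ColumnScaler(kind=scaling).fit(X) if scaling else None
        return FeatureMatrix(
            X=X, columns=list(columns), t_index=tt.ravel(), r_index=rr.ravel(), scaler=scaler
        )


def assemble_feature_matrix(
    fields: Sequence[SpatioTemporalField],
    window=None,
    delay: DelaySpec | None = None,
    stride=(1, 1),
    scaling: str | None = "zscore",
) -> FeatureMatrix:
    """Build the default operator feature matrix (u, ∇u·r̂, Δu per field).

    With a delay, the same three operators of each field at the delayed time
    are appended (suffix ``_lagK``).
    """
    table = FeatureTable(fields, delay=delay)
    columns: list[str] = []
    for f in fields:
        columns += [f.name, f"grad_{f.name}", f"lap_{f.name}"]
    if delay is not None:
        for lag in range(1, delay.n_delays + 1):
            for f in fields:
                columns += [f"{f.name}_lag{lag}", f"grad_{f.name}_lag{lag}", f"lap_{f.name}_lag{lag}"]
    return table.matrix(columns, window=window, stride=stride, scaling=scaling)
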