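"""Forward integration of learned models and error reporting.

Continuous models are integrated by the stiff BDF solver on the learned
method-of-lines system with mirror-ghost no-flux operators; discrete delay
models step by forward Euler with the training delay; experimental-style
rollouts may project the learned time derivative on a stored SVD basis and
impose data corridors at the sub-domain edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import diags

from .features import operators_no_flux
from .models import LearnedPDEModel
from .simulate import RadialGrid, SpatioTemporalField, f2_uptake

__all__ = [
    "RolloutConfig",
    "integrate_continuous",
    "step_delay",
    "svd_project",
    "svd_basis",
    "relative_error_map",
    "peak_locations",
    "RolloutError",
]


class RolloutError(RuntimeError):
    pass


@dataclass
class RolloutConfig:
    rtol: float = 1e-4
    atol: float = 1e-7
    bc_mode: str = "no_flux"  # or "data_corridor"
    corridor_width: int = 5  # grid points per side (data_corridor mode)
    svd_rank: int | None = None
    svd_basis: np.ndarray | None = None  # (n_r, k) left singular vectors
    support_margin: float = 0.25
    max_step: float | None = None
    # surrogates are undefined on negative densities/concentrations; evaluate
    # their features on the non-negativity-projected state
    clamp_nonnegative: bool = True
    # None: BDF for the stiff field models, RK45 for the (non-stiff)
    # second-order-in-time model and whenever the SVD filter densifies the
    # Jacobian structure
    method: str | None = None

    def resolve_method(self, kind: str) -> str:
        if self.method is not None:
            return self.method
        if kind == "second_order" or self.svd_rank is not None:
            return "RK45"
        return "BDF"

    def __post_init__(self):
        if self.bc_mode not in ("no_flux", "data_corridor"):
            raise ValueError(f"unknown bc_mode {self.bc_mode!r}")
        if self.svd_rank is not None:
            if self.svd_basis is None:
                raise ValueError("svd_rank given without svd_basis")
            if self.svd_rank > self.svd_basis.shape[1]:
                raise ValueError("svd_rank exceeds the stored basis size")


# --------------------------------------------------------------------------- #
# SVD filtering
# --------------------------------------------------------------------------- #


def svd_basis(u_t_matrix: np.ndarray, rank: int | None = None):
    """Left singular vectors (and singular values) of a (time × space) u_t set.

    Vectors live in space (columns index the modes): snapshots are the rows,
    so the returned basis spans spatial profiles of the time derivative.
    """
    U, s, Vt = np.linalg.svd(np.asarray(u_t_matrix, dtype=float).T, full_matrices=False)
    if rank is not None:
        U = U[:, :rank]
        s = s[:rank]
    return U, s


def svd_project(u_t_snapshot: np.ndarray, basis: np.ndarray, rank: int | None = None):
    """Orthogonal projection of a field row onto the leading basis vectors."""
    basis = np.asarray(basis, dtype=float)
    if rank is not None:
        if rank > basis.shape[1]:
            raise ValueError(f"rank {rank} exceeds basis size {basis.shape[1]}")
        basis = basis[:, :rank]
    u = np.asarray(u_t_snapshot, dtype=float)
    return basis @ (basis.T @ u)


# --------------------------------------------------------------------------- #
# continuous rollout
# --------------------------------------------------------------------------- #


def _band_sparsity(n_state: int, bandwidth: int = 6):
    bandwidth = min(bandwidth, n_state - 1)
    offsets = range(-bandwidth, bandwidth + 1)
    return diags([np.ones(n_state - abs(k)) for k in offsets], list(offsets), format="csr")


def _continuous_rhs(
    model: LearnedPDEModel,
    grid: RadialGrid,
    config: RolloutConfig,
    state_fields,
    compose=None,
    restrict=None,
):
    """Build the learned method-of-lines right-hand side.

    state_fields: ("b", "c") for full/single/gray, ("b", "v") for second_order.
    ``compose(t, u0, u1)`` may embed the evolving interior into a profile with
    data-supplied corridor nodes; ``restrict`` maps full-profile rates back to
    the evolving subset.
    """
    kind = model.kind
    sim = model.sim_config
    support_warned = [False]

    def maybe_filter(du):
        if config.svd_rank is not None:
            return svd_project(du, config.svd_basis, config.svd_rank)
        return du

    def rhs(t, y):
        u0 = y[0::2]
        u1 = y[1::2]
        if compose is not None:
            u0, u1 = compose(t, u0, u1)
        g0, l0 = operators_no_flux(u0, grid)
        if kind == "second_order":
            u0f = np.maximum(u0, 0.0) if config.clamp_nonnegative else u0
            g0f, l0f = operators_no_flux(u0f, grid) if config.clamp_nonnegative else (g0, l0)
            X = np.column_stack([u0f, g0f, l0f, u1])
            if not np.all(np.isfinite(X)):
                raise RolloutError("non-finite features during rollout (support violation)")
            rate0 = u1
            rate1 = maybe_filter(model.predict_targets(X)[:, 0])
        else:
            g1, l1 = operators_no_flux(u1, grid)
            if config.clamp_nonnegative:
                u0f = np.maximum(u0, 0.0)
                u1f = np.maximum(u1, 0.0)
                g0f, l0f = operators_no_flux(u0f, grid)
                g1f, l1f = operators_no_flux(u1f, grid)
            else:
                u0f, u1f, g0f, l0f, g1f, l1f = u0, u1, g0, l0, g1, l1
            X = np.column_stack([u0f, g0f, l0f, u1f, g1f, l1f])
            if not np.all(np.isfinite(X)):
                raise RolloutError("non-finite features during rollout (support violation)")
            if not support_warned[0]:
                frac = model.support_fraction(X, config.support_margin)
                if frac < 0.5:
                    warnings.warn(
                        f"only {frac:.0%} of rollout inputs lie near the training support"
                    )
                support_warned[0] = True
            pred = model.predict_targets(X)
            if kind == "blackbox_full":
                rate0 = maybe_filter(pred[:, 0])
                rate1 = maybe_filter(pred[:, 1])
            elif kind == "blackbox_single":
                rate0 = maybe_filter(pred[:, 0])
                rate1 = sim.D_c * l1 - sim.kappa * u0 * f2_uptake(np.maximum(u1, 0.0), sim.c_char)
            elif kind == "graybox":
                D_b = model.spec.known_constants["D_b"]
                rate0 = maybe_filter(D_b * l0 + pred[:, 0])
                rate1 = sim.D_c * l1 - sim.kappa * u0 * f2_uptake(np.maximum(u1, 0.0), sim.c_char)
            else:
                raise RolloutError(f"kind {kind!r} is not a continuous-time model")
        if restrict is not None:
            rate0, rate1 = restrict(rate0), restrict(rate1)
        dy = np.empty(2 * rate0.size)
        dy[0::2] = rate0
        dy[1::2] = rate1
        return dy

    return rhs


def _interp_rows(t, times, data):
    """Linear time interpolation between stored data rows."""
    pos = np.interp(t, times, np.arange(times.size))
    k = min(int(pos), times.size - 2)
    w = pos - k
    return (1 - w) * data[k] + w * data[k + 1]


def integrate_continuous(
    model: LearnedPDEModel,
    init: dict,
    times: np.ndarray,
    config: RolloutConfig | None = None,
    grid: RadialGrid | None = None,
    corridor_data: dict | None = None,
    known_c: np.ndarray | None = None,
):
    """Integrate a continuous learned model over the given report times.

    ``init`` maps state names to initial rows: {"b": row, "c": row} for the
    field models, {"b": row, "v": row} for the second-order model.

    In data-corridor mode ``corridor_data`` supplies per-state
    (n_times × n_r) arrays; the outer ``corridor_width`` grid points (and the
    inner ones too when the grid does not start at r = 0) are held at the
    time-interpolated data while only the complementary interior evolves.
    The returned fields contain the corridor data at the corridor nodes.
    """
    config = config or RolloutConfig()
    grid = grid or model.grid
    times = np.asarray(times, dtype=float)
    kind = model.kind
    if kind in ("delay_blackbox", "delay_graybox"):
        raise RolloutError("use step_delay for discrete delay models")
    names = ("b", "v") if kind == "second_order" else ("b", "c")
    if kind in ("blackbox_single", "graybox") and model.sim_config is None:
        raise RolloutError(f"{kind} rollout needs sim_config for the analytic c dynamics")
    for name in names:
        if name not in init:
            raise ValueError(f"initial state missing field {name!r}")

    n = grid.n
    if known_c is not None:
        if kind not in ("blackbox_single", "graybox"):
            raise RolloutError("known_c applies only to the single-PDE models (c field known)")
        known_c = np.asarray(known_c, dtype=float)
        if known_c.shape != (times.size, n):
            raise ValueError("known_c must be (n_times, n_r) on the rollout grid/times")
    init0 = np.asarray(init[names[0]], dtype=float)

    # corridor partition (Dirichlet data nodes vs evolving interior)
    if config.bc_mode == "no_flux":
        evolving = np.arange(n)
    else:
        if corridor_data is None:
            raise ValueError("data_corridor mode requires corridor_data")
        needed = [names[0]] if known_c is not None else list(names)
        for name in needed:
            if name not in corridor_data:
                raise ValueError(f"corridor_data missing field {name!r}")
            if corridor_data[name].shape != (times.size, n):
                raise ValueError("corridor data must be (n_times, n_r) on the rollout grid/times")
        w = config.corridor_width
        edge = list(range(n - w, n))
        if grid.r[0] > 1e-12:  # origin-excluded sub-domain: corridor on both sides
            edge = list(range(w)) + edge
        edge = np.asarray(edge)
        evolving = np.setdiff1d(np.arange(n), edge)

    if known_c is not None:
        # only b evolves; c and its operators come from the known trajectory
        sim = model.sim_config
        D_b = model.spec.known_constants.get("D_b")

        def rhs(t, y):
            if config.bc_mode == "no_flux":
                u0 = y
            else:
                u0 = _interp_rows(t, times, corridor_data["b"]).copy()
                u0[evolving] = y
            c_row = _interp_rows(t, times, known_c)
            g0, l0 = operators_no_flux(u0, grid)
            u0f = np.maximum(u0, 0.0) if config.clamp_nonnegative else u0
            g0f, l0f = operators_no_flux(u0f, grid) if config.clamp_nonnegative else (g0, l0)
            g1, l1 = operators_no_flux(c_row, grid)
            X = np.column_stack([u0f, g0f, l0f, c_row, g1, l1])
            if not np.all(np.isfinite(X)):
                raise RolloutError("non-finite features during rollout (support violation)")
            pred = model.predict_targets(X)[:, 0]
            rate = pred if kind == "blackbox_single" else D_b * l0 + pred
            if config.svd_rank is not None:
                rate = svd_project(rate, config.svd_basis, config.svd_rank)
            return rate[evolving]

        method = config.resolve_method(kind)
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            init0[evolving],
            method=method,
            t_eval=times,
            rtol=config.rtol,
            atol=config.atol,
            max_step=config.max_step or np.inf,
            **({"jac_sparsity": _band_sparsity(evolving.size, 3)} if method == "BDF" else {}),
        )
        if not sol.success:
            raise RolloutError(
                f"integration failed at t={sol.t[-1] if sol.t.size else times[0]:.2f}: {sol.message}"
            )
        out0 = np.empty((times.size, n))
        if config.bc_mode == "no_flux":
            out0[:] = sol.y.T
        else:
            out0[:] = corridor_data["b"]
            out0[:, evolving] = sol.y.T
        f0 = SpatioTemporalField(out0, times, grid, name="b")
        f1 = SpatioTemporalField(known_c.copy(), times, grid, name="c")
        return f0, f1

    init1 = np.asarray(init[names[1]], dtype=float)
    if config.bc_mode == "no_flux":
        compose = restrict = None
    else:
        data0 = corridor_data[names[0]]
        data1 = corridor_data[names[1]]

        def compose(t, u0_in, u1_in):
            full0 = _interp_rows(t, times, data0).copy()
            full1 = _interp_rows(t, times, data1).copy()
            full0[evolving] = u0_in
            full1[evolving] = u1_in
            return full0, full1

        def restrict(rate):
            return rate[evolving]

    y0 = np.empty(2 * evolving.size)
    y0[0::2] = init0[evolving]
    y0[1::2] = init1[evolving]
    rhs = _continuous_rhs(model, grid, config, names, compose=compose, restrict=restrict)
    method = config.resolve_method(kind)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method=method,
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step or np.inf,
        **({"jac_sparsity": _band_sparsity(2 * evolving.size)} if method == "BDF" else {}),
    )
    if not sol.success:
        raise RolloutError(
            f"integration failed at t={sol.t[-1] if sol.t.size else times[0]:.2f}: {sol.message}"
        )
    out0 = np.empty((times.size, n))
    out1 = np.empty((times.size, n))
    if config.bc_mode == "no_flux":
        out0[:] = sol.y[0::2, :].T
        out1[:] = sol.y[1::2, :].T
    else:
        out0[:] = corridor_data[names[0]]
        out1[:] = corridor_data[names[1]]
        out0[:, evolving] = sol.y[0::2, :].T
        out1[:, evolving] = sol.y[1::2, :].T

    f0 = SpatioTemporalField(out0, times, grid, name=names[0])
    f1 = SpatioTemporalField(out1, times, grid, name=names[1])
    return f0, f1


# --------------------------------------------------------------------------- #
# delay stepping
# --------------------------------------------------------------------------- #


def step_delay(
    model: LearnedPDEModel,
    history: tuple[np.ndarray, np.ndarray],
    n_steps: int,
    history_dt: float | None = None,
):
    """Iterate the forward-Euler delay stepper for n_steps.

    ``history`` is (b at t_{k−1}, b at t_k); the step size equals the
    training delay and a differing ``history_dt`` is refused. Returns the
    trajectory including the two history rows, shape (n_steps + 2, n_r).
    """
    if model.kind not in ("delay_blackbox", "delay_graybox"):
        raise RolloutError("step_delay requires a delay model")
    dt = model.report_dt
    if history_dt is not None and abs(history_dt - dt) > 1e-9:
        raise RolloutError(
            f"history spacing {history_dt} differs from the training delay {dt}; "
            "delay models only step at their training delay"
        )
    grid = model.grid
    b_prev = np.asarray(history[0], dtype=float)
    b_curr = np.asarray(history[1], dtype=float)
    if b_prev.shape != (grid.n,) or b_curr.shape != (grid.n,):
        raise ValueError("history rows must match the model grid")
    D_b = model.spec.known_constants.get("D_b")
    if D_b is not None and D_b * dt / grid.dr**2 > 0.5:
        warnings.warn(
            f"explicit diffusion step D_b·Δt/dr² = {D_b * dt / grid.dr**2:.2f} exceeds the "
            "stability limit 0.5"
        )
    traj = np.empty((n_steps + 2, grid.n))
    traj[0] = b_prev
    traj[1] = b_curr
    for k in range(n_steps):
        g_now, l_now = operators_no_flux(b_curr, grid)
        g_old, l_old = operators_no_flux(b_prev, grid)
        X = np.column_stack([b_curr, g_now, l_now, b_prev, g_old, l_old])
        f = model.predict_targets(X)[:, 0]
        if model.kind == "delay_graybox":
            f = f + D_b * l_now
        b_next = b_curr + dt * f
        if not np.all(np.isfinite(b_next)):
            raise RolloutError(f"delay rollout diverged at step {k}")
        traj[k + 2] = b_next
        b_prev, b_curr = b_curr, b_next
    return traj


# --------------------------------------------------------------------------- #
# error reporting
# --------------------------------------------------------------------------- #


def relative_error_map(
    pred: SpatioTemporalField | np.ndarray,
    truth: SpatioTemporalField | np.ndarray,
    floor: float | None = None,
):
    """100·|pred − truth| / max(|truth|, floor), elementwise (percent).

    The floor guards near-zero truth regions; it defaults to 5% of the
    maximum |truth|.
    """
    p = pred.values if isinstance(pred, SpatioTemporalField) else np.asarray(pred, dtype=float)
    t = truth.values if isinstance(truth, SpatioTemporalField) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if floor is None:
        floor = 0.05 * float(np.abs(t).max())
    if floor <= 0:
        raise ValueError("floor must be positive")
    return 100.0 * np.abs(p - t) / np.maximum(np.abs(t), floor)


def peak_locations(field: SpatioTemporalField) -> np.ndarray:
    """Radius of the field maximum at each time (parabolic sub-grid refinement)."""
    vals = field.values
    r = field.grid.r
    idx = np.argmax(vals, axis=1)
    locs = r[idx].astype(float)
    for k, i in enumerate(idx):
        if 0 < i < r.size - 1:
            y0, y1, y2 = vals[k, i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-30:
                locs[k] = r[i] + 0.5 * (y0 - y2) / denom * field.grid.dr
    return locs
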