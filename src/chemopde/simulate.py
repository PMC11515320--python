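"""Ground-truth simulator for the extended Keller–Segel chemotaxis system.

Solves, on a 1-D radial (or Cartesian) grid with no-flux boundaries,

    b_t = D_b Δb − χ0 ∇·[b ∇ log F1(c)] + γ b F2(c)
    c_t = D_c Δc − κ b F2(c)

with F1(c) = (1 + c/c−)/(1 + c/c+) (logarithmic-sensing response) and
F2(c) = c/(c + c_char) (Monod uptake).  The discretization is a
conservative finite-volume method of lines: with γ = 0 the discrete
bacterial mass is conserved up to integrator tolerance, and the total
nutrient is non-increasing.

Units: lengths µm, times s, bacterial density 1/µm³, nutrient µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import diags

__all__ = [
    "SimulationConfig",
    "RadialGrid",
    "SpatioTemporalField",
    "f1_sensing",
    "f2_uptake",
    "log_f1",
    "chemotactic_term",
    "chemotactic_term_pointwise",
    "analytic_b_t",
    "analytic_c_t",
    "simulate_ks",
    "radial_mass",
    "IntegrationError",
]

CoordinateMode = Literal["cylindrical-radial", "cartesian-1d"]


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails or the solution blows up."""


# --------------------------------------------------------------------------- #
# grids and fields
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class RadialGrid:
    """Uniform 1-D grid, usually starting at the symmetry axis r = 0.

    Sub-domain grids excluding the origin (r[0] > 0) are allowed; the
    symmetry-axis limits of the operators then do not apply.
    """

    r: np.ndarray
    dr: float
    coordinate_mode: CoordinateMode = "cylindrical-radial"

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("grid needs at least 2 points")
        if r[0] < -1e-12:
            raise ValueError("grid must not contain negative radii")
        spacing = np.diff(r)
        if not np.allclose(spacing, self.dr, rtol=1e-12, atol=1e-12 * max(self.dr, 1.0)):
            raise ValueError("grid spacing is not uniform")
        if self.coordinate_mode not in ("cylindrical-radial", "cartesian-1d"):
            raise ValueError(f"unknown coordinate_mode {self.coordinate_mode!r}")

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def starts_at_origin(self) -> bool:
        return abs(self.r[0]) < 1e-12

    @classmethod
    def regular(cls, R: float, dr: float, coordinate_mode: CoordinateMode = "cylindrical-radial") -> "RadialGrid":
        n = int(round(R / dr)) + 1
        if abs(n - 1 - R / dr) > 1e-9:
            raise ValueError("R must be an integer multiple of dr")
        return cls(r=np.linspace(0.0, R, n), dr=dr, coordinate_mode=coordinate_mode)

    def cell_volumes(self) -> np.ndarray:
        """Per-node control-volume weights (per radian / unit height).

        Cylindrical mode integrates u r dr exactly over the control volumes;
        Cartesian mode integrates u dr.
        """
        r, dr = self.r, self.dr
        lo = np.maximum(r - dr / 2.0, 0.0)
        hi = np.minimum(r + dr / 2.0, r[-1])
        if self.coordinate_mode == "cylindrical-radial":
            return (hi**2 - lo**2) / 2.0
        return hi - lo

    def face_areas(self) -> np.ndarray:
        """Interface weights at the n−1 interior faces."""
        faces = (self.r[:-1] + self.r[1:]) / 2.0
        if self.coordinate_mode == "cylindrical-radial":
            return faces
        return np.ones_like(faces)


@dataclass
class SpatioTemporalField:
    """One scalar field sampled on (time × space)."""

    values: np.ndarray  # (n_times, n_r)
    times: np.ndarray  # seconds
    grid: RadialGrid
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (self.times.size, self.grid.n):
            raise ValueError(
                f"field shape {self.values.shape} != (n_times={self.times.size}, n_r={self.grid.n})"
            )

    @property
    def report_dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window_indices(self, t_range=None, r_range=None):
        """Index arrays of times/radii falling inside the closed ranges."""
        tol = 1e-9
        t_idx = np.arange(self.times.size)
        r_idx = np.arange(self.grid.n)
        if t_range is not None:
            t0, t1 = t_range
            t_idx = t_idx[(self.times >= t0 - tol) & (self.times <= t1 + tol)]
        if r_range is not None:
            r0, r1 = r_range
            r_idx = r_idx[(self.grid.r >= r0 - tol) & (self.grid.r <= r1 + tol)]
        return t_idx, r_idx


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class SimulationConfig:
    """Physical and numerical parameters of the extended Keller–Segel run.

    Defaults reproduce the published traveling-band simulation: note the
    domain radius is the 1000 µm simulation domain (the experimental chamber
    is much larger but is not what the training windows live in), and the
    initial nutrient concentration is 10 mM = 1e4 µM.
    """

    D_b: float = 2.325  # µm²/s
    chi0: float = 17.9  # µm²/s
    c_minus: float = 1.0  # µM
    c_plus: float = 30.0  # µM
    c_char: float = 1.0  # µM
    gamma: float = 0.0  # growth coefficient (paper value 0)
    D_c: float = 800.0  # µm²/s
    kappa: float = 3000.0  # consumption coefficient, µM µm³/s per cell
    b0: float = 0.95  # 1/µm³
    sigma: float = 42.62  # µm (initial Gaussian width)
    c0: float = 10000.0  # µM
    R_domain: float = 1000.0  # µm
    dr: float = 2.0  # µm
    t_end: float = 300.0  # s
    report_dt: float = 0.5  # s
    rtol: float = 1e-7
    atol: float = 1e-9
    coordinate_mode: CoordinateMode = "cylindrical-radial"

    def __post_init__(self):
        if self.D_b <= 0 or self.D_c <= 0:
            raise ValueError("diffusivities must be positive")
        if not (self.c_plus > self.c_minus > 0):
            raise ValueError("require c_plus > c_minus > 0")
        if self.c_char <= 0:
            raise ValueError("c_char must be positive")
        if self.gamma < 0 or self.kappa < 0:
            raise ValueError("gamma and kappa must be non-negative")
        if self.dr <= 0:
            raise ValueError("dr must be positive")
        n_cells = self.R_domain / self.dr
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("R_domain must be an integer multiple of dr")
        if self.report_dt <= 0 or self.t_end <= 0:
            raise ValueError("time parameters must be positive")

    def grid(self) -> RadialGrid:
        return RadialGrid.regular(self.R_domain, self.dr, self.coordinate_mode)

    @classmethod
    def paper_fidelity(cls, **overrides) -> "SimulationConfig":
        """High-resolution mode (dr = 0.5 µm, reports every 0.1 s)."""
        params = dict(dr=0.5, report_dt=0.1)
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------- #
# response functions and analytic terms
# --------------------------------------------------------------------------- #


def _check_nonnegative(c, what="c"):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"{what} must be non-negative")
    return c


def f1_sensing(c, c_minus: float, c_plus: float):
    """Logarithmic-sensing response F1(c) = (1 + c/c−)/(1 + c/c+).

    Strictly increasing from 1 at c = 0 to c_plus/c_minus as c → ∞.
    """
    if not (c_plus > c_minus > 0):
        raise ValueError("require c_plus > c_minus > 0")
    c = _check_nonnegative(c)
    return (1.0 + c / c_minus) / (1.0 + c / c_plus)


def f2_uptake(c, c_char: float):
    """Monod uptake saturation F2(c) = c/(c + c_char) ∈ [0, 1)."""
    if c_char <= 0:
        raise ValueError("c_char must be positive")
    c = _check_nonnegative(c)
    return c / (c + c_char)


def log_f1(c, c_minus: float, c_plus: float):
    """log F1(c), written to stay accurate for c spanning many decades."""
    if not (c_plus > c_minus > 0):
        raise ValueError("require c_plus > c_minus > 0")
    c = np.asarray(c, dtype=float)
    return np.log1p(c / c_minus) - np.log1p(c / c_plus)


def _dlog_f1_dc(c, c_minus, c_plus):
    return 1.0 / (c_minus + c) - 1.0 / (c_plus + c)


def _d2log_f1_dc2(c, c_minus, c_plus):
    return -1.0 / (c_minus + c) ** 2 + 1.0 / (c_plus + c) ** 2


def chemotactic_term_pointwise(b, grad_b, c, grad_c, lap_c, chi0, c_minus, c_plus):
    """−χ0 ∇·[b ∇ log F1(c)] expanded by the chain rule into local operators.

    With φ(c) = d log F1/dc the term equals
    −χ0 [ φ(c) ∇b·∇c + b (φ′(c) |∇c|² + φ(c) Δc) ], a pointwise function of
    (b, ∇b, c, ∇c, Δc).  This is the analytic oracle used for gray-box
    training targets and the parametric sensing-bound dataset.
    """
    c = np.asarray(c, dtype=float)
    phi = _dlog_f1_dc(c, c_minus, c_plus)
    dphi = _d2log_f1_dc2(c, c_minus, c_plus)
    return -chi0 * (phi * grad_b * grad_c + b * (dphi * grad_c**2 + phi * lap_c))


def analytic_b_t(b, grad_b, lap_b, c, grad_c, lap_c, config: SimulationConfig):
    """Ground-truth right-hand side of the b equation as a pointwise map."""
    chem = chemotactic_term_pointwise(
        b, grad_b, c, grad_c, lap_c, config.chi0, config.c_minus, config.c_plus
    )
    growth = config.gamma * b * f2_uptake(np.maximum(c, 0.0), config.c_char)
    return config.D_b * lap_b + chem + growth


def analytic_c_t(b, c, lap_c, config: SimulationConfig):
    """Ground-truth right-hand side of the c equation as a pointwise map."""
    return config.D_c * lap_c - config.kappa * b * f2_uptake(np.maximum(c, 0.0), config.c_char)


def chemotactic_term(b, c, grid: RadialGrid, chi0: float, c_minus: float, c_plus: float):
    """−χ0 ∇·[b ∇ log F1(c)] evaluated by discrete divergence on the grid.

    Accepts 1-D rows or (time × space) arrays; uses the grid's coordinate
    mode (cylindrical divergence carries the 1/r weighting with the
    symmetry limit at the origin).
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if b.shape != c.shape or b.shape[-1] != grid.n:
        raise ValueError(f"b {b.shape} and c {c.shape} must share the grid ({grid.n} points)")
    if np.any(c < 0):
        raise ValueError("c must be non-negative")
    from .features import radial_gradient, divergence_radial

    L = log_f1(c, c_minus, c_plus)
    out = np.empty_like(b)
    for k in range(b.shape[0]):
        v = b[k] * radial_gradient(L[k], grid)
        out[k] = -chi0 * divergence_radial(v, grid)
    return out[0] if out.shape[0] == 1 else out


# --------------------------------------------------------------------------- #
# the solver
# --------------------------------------------------------------------------- #


def _rhs_factory(config: SimulationConfig, grid: RadialGrid):
    n = grid.n
    dr = grid.dr
    area = grid.face_areas()
    vol = grid.cell_volumes()
    D_b, D_c = config.D_b, config.D_c
    chi0, kappa, gamma = config.chi0, config.kappa, config.gamma
    cm, cp, cc = config.c_minus, config.c_plus, config.c_char

    def rhs(t, y):
        b = y[0::2]
        c = y[1::2]
        c_pos = np.maximum(c, 0.0)  # solver wiggle below 0 stays out of the nonlinearities
        L = log_f1(c_pos, cm, cp)
        # face fluxes (n−1 interior faces); boundary faces carry zero flux
        db = np.diff(b) / dr
        dL = np.diff(L) / dr
        b_face = 0.5 * (b[:-1] + b[1:])
        flux_b = D_b * db - chi0 * b_face * dL
        flux_c = D_c * np.diff(c) / dr
        dydt = np.empty_like(y)
        f2 = c_pos / (c_pos + cc)
        div_b = np.empty(n)
        div_c = np.empty(n)
        af_b = area * flux_b
        af_c = area * flux_c
        div_b[0] = af_b[0] / vol[0]
        div_b[1:-1] = (af_b[1:] - af_b[:-1]) / vol[1:-1]
        div_b[-1] = -af_b[-1] / vol[-1]
        div_c[0] = af_c[0] / vol[0]
        div_c[1:-1] = (af_c[1:] - af_c[:-1]) / vol[1:-1]
        div_c[-1] = -af_c[-1] / vol[-1]
        dydt[0::2] = div_b + gamma * b * f2
        dydt[1::2] = div_c - kappa * b * f2
        return dydt

    return rhs


def _jac_sparsity(n: int):
    """Banded dependency pattern of the interleaved (b, c) state."""
    m = 2 * n
    offsets = range(-3, 4)
    return diags([np.ones(m - abs(k)) for k in offsets], list(offsets), format="csr")


def simulate_ks(config: SimulationConfig):
    """Integrate the chemotaxis system; returns (b, c) spatiotemporal fields.

    Method-of-lines with the BDF stiff integrator; output reported every
    ``config.report_dt`` seconds from 0 to ``config.t_end``.
    """
    grid = config.grid()
    r = grid.r
    b_init = config.b0 * np.exp(-(r**2) / (2.0 * config.sigma**2))
    c_init = np.full(grid.n, config.c0)
    y0 = np.empty(2 * grid.n)
    y0[0::2] = b_init
    y0[1::2] = c_init

    n_report = int(round(config.t_end / config.report_dt)) + 1
    times = np.linspace(0.0, config.t_end, n_report)
    rhs = _rhs_factory(config, grid)
    sol = solve_ivp(
        rhs,
        (0.0, config.t_end),
        y0,
        method="BDF",
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
        jac_sparsity=_jac_sparsity(grid.n),
    )
    if not sol.success:
        raise IntegrationError(f"BDF integration failed: {sol.message}")

    b_vals = sol.y[0::2, :].T
    c_vals = sol.y[1::2, :].T
    slack = 1000.0 * max(config.atol, config.rtol * config.c0)
    if b_vals.min() < -slack or c_vals.min() < -slack:
        raise IntegrationError(
            f"negative fields beyond tolerance slack (min b={b_vals.min():.3g}, min c={c_vals.min():.3g})"
        )
    b = SpatioTemporalField(b_vals, times, grid, name="b", units="1/µm³")
    c = SpatioTemporalField(np.maximum(c_vals, 0.0), times, grid, name="c", units="µM")
    return b, c


def radial_mass(field: SpatioTemporalField) -> np.ndarray:
    """Discrete total content ∫ u r dr (or ∫ u dr in Cartesian mode) per time."""
    return field.values @ field.grid.cell_volumes()
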