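"""Experimental-style data emulation and processing.

Generates a degraded, noisy, b-only fixture from simulator output
(standing in for azimuthally averaged confocal fluorescence), then
smooths it in space (Savitzky–Golay + Gaussian), interpolates it in time
with Gaussian radial basis functions, and partitions the domain into
origin exclusion / boundary corridors / training complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

from .simulate import RadialGrid, SpatioTemporalField

__all__ = [
    "ExperimentalFixtureConfig",
    "make_experimental_fixture",
    "smooth_profiles",
    "interpolate_time_rbf",
    "TrainingPartition",
    "select_training_window",
]


@dataclass
class ExperimentalFixtureConfig:
    """Degradation recipe emulating the confocal measurement geometry."""

    dr: float = 2.48  # µm
    dt: float = 600.0  # s (10 min in the real experiment)
    sigma_rel: float = 0.05  # multiplicative Gaussian noise level
    hide_c: bool = True
    origin_mask_radius: float = 50.0  # µm
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if self.dr <= 0 or self.dt <= 0:
            raise ValueError("dr and dt must be positive")


def make_experimental_fixture(
    b: SpatioTemporalField,
    c: SpatioTemporalField | None,
    config: ExperimentalFixtureConfig,
) -> SpatioTemporalField:
    """Degrade a simulated b field to experimental-like sampling and noise.

    Time is subsampled to multiples of ``config.dt`` (must align with the
    source report interval); space is linearly resampled onto a grid of
    spacing ``config.dr``; multiplicative Gaussian noise of relative level
    ``sigma_rel`` is applied. The c field is withheld (hide_c).
    """
    src_dt = b.report_dt
    k = config.dt / src_dt
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"fixture dt {config.dt} must be a positive integer multiple of the "
            f"source report interval {src_dt}"
        )
    k = int(round(k))
    if k >= b.times.size:
        raise ValueError("fixture dt is coarser than the source time span")
    t_idx = np.arange(0, b.times.size, k)

    R = b.grid.r[-1]
    n_new = int(np.floor(R / config.dr)) + 1
    r_new = np.arange(n_new) * config.dr
    grid_new = RadialGrid(r=r_new, dr=config.dr, coordinate_mode=b.grid.coordinate_mode)

    rng = np.random.default_rng(config.seed)
    vals = np.empty((t_idx.size, n_new))
    for i, ti in enumerate(t_idx):
        vals[i] = np.interp(r_new, b.grid.r, b.values[ti])
    noise = rng.standard_normal(vals.shape)
    vals = vals * (1.0 + config.sigma_rel * noise)

    return SpatioTemporalField(vals, b.times[t_idx], grid_new, name="b", units=b.units)


def smooth_profiles(
    b: SpatioTemporalField,
    savgol_window: int = 7,
    savgol_order: int = 3,
    gaussian_sigma: float = 0.75,
) -> SpatioTemporalField:
    """Per-snapshot spatial smoothing: Savitzky–Golay, then Gaussian kernel.

    ``gaussian_sigma`` is in grid points; 0 disables the Gaussian stage.
    """
    if savgol_window % 2 == 0:
        raise ValueError("savgol_window must be odd")
    if savgol_order >= savgol_window:
        raise ValueError("savgol_order must be smaller than savgol_window")
    vals = savgol_filter(b.values, savgol_window, savgol_order, axis=1, mode="interp")
    if gaussian_sigma > 0:
        vals = gaussian_filter1d(vals, gaussian_sigma, axis=1, mode="nearest")
    return SpatioTemporalField(vals, b.times, b.grid, name=b.name, units=b.units)


def interpolate_time_rbf(
    b: SpatioTemporalField,
    target_times,
    shape: float | None = None,
    ridge: float = 1e-8,
) -> SpatioTemporalField:
    """Gaussian-RBF interpolation in time, per space point.

    Exact at the coarse nodes up to the small ridge regularization; refuses
    extrapolation. The kernel is exp(−(ε Δt)²) with shape ε defaulting to
    the reciprocal of the coarse spacing (wider kernels oversmooth a
    traveling front).
    """
    t_coarse = b.times
    if t_coarse.size < 3:
        raise ValueError("need at least 3 coarse time points")
    target_times = np.asarray(target_times, dtype=float)
    if target_times.min() < t_coarse[0] - 1e-9 or target_times.max() > t_coarse[-1] + 1e-9:
        raise ValueError("target times outside the coarse span (extrapolation refused)")
    if shape is None:
        shape = 1.0 / float(np.median(np.diff(t_coarse)))
    K = np.exp(-((shape * (t_coarse[:, None] - t_coarse[None, :])) ** 2))
    Ks = np.exp(-((shape * (target_times[:, None] - t_coarse[None, :])) ** 2))
    # de-mean per space point: a plain Gaussian RBF does not reproduce
    # constants between nodes, the residual interpolant does
    mean = b.values.mean(axis=0)
    W = np.linalg.solve(K + ridge * np.eye(t_coarse.size), b.values - mean)
    vals = Ks @ W + mean
    return SpatioTemporalField(vals, target_times, b.grid, name=b.name, units=b.units)


@dataclass
class TrainingPartition:
    """Disjoint split of the spatial indices within a training window."""

    origin_idx: np.ndarray
    corridor_low_idx: np.ndarray
    corridor_high_idx: np.ndarray
    training_idx: np.ndarray
    corridor_values: np.ndarray  # (n_times, n_r) data rows (for boundary imposition)
    t_idx: np.ndarray

    def __post_init__(self):
        pools = [self.origin_idx, self.corridor_low_idx, self.corridor_high_idx, self.training_idx]
        joined = np.concatenate(pools)
        if joined.size != np.unique(joined).size:
            raise ValueError("partition regions overlap")


def select_training_window(
    b: SpatioTemporalField,
    corridor_width: int = 5,
    origin_exclusion: float = 50.0,
    t_range=None,
    r_range=None,
) -> TrainingPartition:
    """Partition the domain into origin exclusion, corridors, and training set.

    Corridors are ``corridor_width`` grid points on each side of the retained
    region (after origin exclusion); their data rows at every window time are
    returned for use as boundary values during rollout.
    """
    t_idx, r_idx = b.window_indices(t_range, r_range)
    r = b.grid.r[r_idx]
    origin_mask = r < origin_exclusion
    origin_idx = r_idx[origin_mask]
    kept = r_idx[~origin_mask]
    if kept.size <= 2 * corridor_width:
        raise ValueError("window too small for the requested corridors")
    corridor_low = kept[:corridor_width]
    corridor_high = kept[-corridor_width:]
    training = kept[corridor_width:-corridor_width]
    return TrainingPartition(
        origin_idx=origin_idx,
        corridor_low_idx=corridor_low,
        corridor_high_idx=corridor_high,
        training_idx=training,
        corridor_values=b.values[t_idx],
        t_idx=t_idx,
    )
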