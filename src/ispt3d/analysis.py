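"""Trajectory statistics and localization-error studies.

Diffusion analysis (time-averaged MSD, linear fits, step-size statistics)
plus the simulation studies that characterize the tracker: axial error
versus particle height and focal plane, versus shot-noise level, and versus
a deliberate lateral-center offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import CameraConfig, OpticalConfig, TrackingConfig
from .optics import (RadialModelStack, build_model_stack,
                     gnp_scatterer_strength, radial_profile_resampled)
from .preprocess import RadialProfileSeries, rvt_localize
from .simulate import Trajectory3D, render_frame
from .axial import track_axial

__all__ = [
    "MSDCurve",
    "ErrorStudyResult",
    "msd",
    "fit_diffusion",
    "step_statistics",
    "axial_error_study",
    "noise_level_study",
    "lateral_offset_study",
]


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement per lag, per axis and 3D."""

    lags: np.ndarray               # s (lag 0 included, MSD 0)
    per_axis: np.ndarray           # (n_lags, n_axes), um^2
    total: np.ndarray              # um^2
    counts: np.ndarray             # displacement pairs per lag


def msd(track: Trajectory3D | np.ndarray, frame_interval: float | None = None,
        max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of a uniformly sampled trajectory.

    ``track`` is a Trajectory3D or an (n, k) position array in nm;
    output units are um^2.
    """
    if isinstance(track, Trajectory3D):
        pos = track.positions
        frame_interval = track.frame_interval
    else:
        pos = np.asarray(track, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
        if frame_interval is None:
            raise ValueError("frame_interval required for a bare array")
    n = pos.shape[0]
    if n < 10:
        raise ValueError("need at least 10 frames for an MSD estimate")
    if max_lag is None:
        max_lag = n // 4
    if max_lag >= n:
        warnings.warn("max_lag clipped to trajectory length - 1")
        max_lag = n - 1
    pos_um = pos / 1_000.0
    lags = np.arange(max_lag + 1)
    per_axis = np.zeros((max_lag + 1, pos.shape[1]))
    counts = np.empty(max_lag + 1, dtype=int)
    counts[0] = n
    for lag in range(1, max_lag + 1):
        d = pos_um[lag:] - pos_um[:-lag]
        per_axis[lag] = np.mean(d * d, axis=0)
        counts[lag] = d.shape[0]
    return MSDCurve(lags=lags * frame_interval, per_axis=per_axis,
                    total=per_axis.sum(axis=1), counts=counts)


@dataclass
class DiffusionFit:
    D: float                       # um^2/s
    intercept: float               # um^2 (2 * sum of per-axis sigma_loc^2 in 3D)
    D_per_axis: np.ndarray
    intercept_per_axis: np.ndarray
    negative_slope: bool = False


def fit_diffusion(curve: MSDCurve, n_fit_points: int = 10) -> DiffusionFit:
    """Least-squares line through the first lags of the MSD.

    3D: slope = 6 D and the intercept estimates ``2 * sum_axes sigma_loc^2``,
    the localization-error offset; per axis: slope = 2 D.
    """
    if n_fit_points < 2:
        raise ValueError("need at least 2 fit points")
    n = min(n_fit_points, curve.lags.size - 1)
    x = curve.lags[1:n + 1]
    slope_t, icpt_t = np.polyfit(x, curve.total[1:n + 1], 1)
    slopes, icpts = np.polyfit(x, curve.per_axis[1:n + 1], 1)
    negative = slope_t < 0
    if negative:
        warnings.warn("negative MSD slope; D reported as 0")
    n_axes = curve.per_axis.shape[1]
    return DiffusionFit(D=max(slope_t, 0.0) / (2 * n_axes),
                        intercept=icpt_t,
                        D_per_axis=np.maximum(slopes, 0.0) / 2.0,
                        intercept_per_axis=icpts,
                        negative_slope=bool(negative))


@dataclass
class StepStatistics:
    interval: float
    sample_std: np.ndarray         # per axis, nm
    gaussian_sigma: np.ndarray     # per axis, nm (ML fit)
    normality_p: np.ndarray
    degenerate: bool = False


def step_statistics(track: Trajectory3D | np.ndarray, interval: float,
                    frame_interval: float | None = None) -> StepStatistics:
    """Per-axis displacement statistics at a chosen time interval.

    ``interval`` must be a multiple of the frame interval.  Returns the
    sample std, a Gaussian maximum-likelihood sigma and a normality-test
    p-value per axis (flagged degenerate for zero-variance axes).
    """
    if isinstance(track, Trajectory3D):
        pos = track.positions
        frame_interval = track.frame_interval
    else:
        pos = np.asarray(track, dtype=float)
    step = int(round(interval / frame_interval))
    if step < 1 or abs(step * frame_interval - interval) > 1e-9 * interval:
        raise ValueError("interval must be a positive multiple of the frame "
                         "interval")
    d = pos[step:] - pos[:-step]
    sample_std = d.std(axis=0, ddof=1)
    degenerate = bool(np.any(sample_std == 0))
    sigma = np.empty(d.shape[1])
    pvals = np.empty(d.shape[1])
    for ax in range(d.shape[1]):
        if sample_std[ax] == 0:
            sigma[ax], pvals[ax] = 0.0, 0.0
            continue
        _, sigma[ax] = stats.norm.fit(d[:, ax])
        pvals[ax] = stats.normaltest(d[:, ax]).pvalue
    return StepStatistics(interval=interval, sample_std=sample_std,
                          gaussian_sigma=sigma, normality_p=pvals,
                          degenerate=degenerate)


# --------------------------------------------------------------------------
# localization-error studies

@dataclass
class ErrorStudyResult:
    """Axial (and optionally lateral) error over a study grid."""

    grid_rows: np.ndarray          # e.g. z_f values or sigma_n levels
    grid_cols: np.ndarray          # z_p values
    axial_std: np.ndarray          # (rows, cols), nm
    axial_bias: np.ndarray
    lateral_std: np.ndarray | None
    n_realizations: int
    n_failures: int
    seed: int

    @property
    def grand_mean(self) -> float:
        return float(np.nanmean(self.axial_std))


def _single_frame_z(image: np.ndarray, center: tuple[float, float],
                    stack: RadialModelStack, n_bins: int, r_max_px: float,
                    tracking: TrackingConfig) -> float:
    prof = radial_profile_resampled(image, center, n_bins, r_max_px,
                                    pixel_size=stack.config.pixel_size_sample)
    series = RadialProfileSeries(frames=np.array([0]), radii=prof.radii,
                                 values=prof.values[None, :])
    result = track_axial(series, stack, threshold=tracking.threshold,
                         refine_window=tracking.refine_window)
    return float(result.z_nm[0])


def axial_error_study(config: OpticalConfig,
                      z_f_values,
                      z_p_values,
                      sigma_n: float,
                      n_realizations: int = 100,
                      seed: int = 0,
                      diameter: float = 40.0,
                      r_max_px: float = 60.0,
                      z_step: float = 1.0,
                      tracking: TrackingConfig = TrackingConfig()
                      ) -> ErrorStudyResult:
    """Axial error of a laterally fixed particle versus (z_f, z_p).

    For every grid cell the noiseless on-axis iPSF is rendered once, then
    ``n_realizations`` shot-noise realizations are localized against a model
    stack for that focal plane; the cell records the standard deviation of
    the retrieved-minus-true heights (and their mean, the bias, separately).
    """
    z_f_values = np.asarray(z_f_values, dtype=float)
    z_p_values = np.asarray(z_p_values, dtype=float)
    strength = gnp_scatterer_strength(diameter, config)
    n_bins = int(r_max_px)
    image_size = 2 * int(np.ceil(r_max_px)) + 1
    center = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    rng = np.random.default_rng(seed)
    std = np.full((z_f_values.size, z_p_values.size), np.nan)
    bias = np.full_like(std, np.nan)
    failures = 0
    z_lo = max(0.0, z_p_values.min() - 200.0)
    z_hi = z_p_values.max() + 200.0
    for i, z_f in enumerate(z_f_values):
        cfg_f = config.replace(focal_plane_z=float(z_f))
        stack = build_model_stack(cfg_f, z_lo, z_hi, z_step, n_bins=n_bins,
                                  r_max_px=r_max_px,
                                  scatterer_strength=strength)
        for j, z_p in enumerate(z_p_values):
            clean = render_frame(cfg_f, (0.0, 0.0, float(z_p)), image_size,
                                 strength)
            errs = []
            for _ in range(n_realizations):
                noisy = clean + rng.normal(0.0, sigma_n, clean.shape) \
                    if sigma_n > 0 else clean
                try:
                    z_hat = _single_frame_z(noisy, center, stack, n_bins,
                                            r_max_px, tracking)
                    errs.append(z_hat - z_p)
                except ValueError:
                    failures += 1
            if errs:
                std[i, j] = float(np.std(errs))
                bias[i, j] = float(np.mean(errs))
    return ErrorStudyResult(grid_rows=z_f_values, grid_cols=z_p_values,
                            axial_std=std, axial_bias=bias, lateral_std=None,
                            n_realizations=n_realizations,
                            n_failures=failures, seed=seed)


def noise_level_study(config: OpticalConfig,
                      sigma_levels,
                      z_p_values,
                      n_realizations: int = 30,
                      seed: int = 0,
                      diameter: float = 40.0,
                      r_max_px: float = 50.0,
                      z_step: float = 1.0,
                      image_size: int = 128,
                      tracking: TrackingConfig = TrackingConfig()
                      ) -> ErrorStudyResult:
    """Axial versus lateral precision as a function of shot-noise level.

    At each noise level and height the frame is localized laterally by the
    radial variance transform and axially by the correlation pipeline (about
    the true center, keeping the two error sources separate); the errors are
    averaged over the height range.
    """
    sigma_levels = np.asarray(sigma_levels, dtype=float)
    z_p_values = np.asarray(z_p_values, dtype=float)
    strength = gnp_scatterer_strength(diameter, config)
    n_bins = int(r_max_px)
    if image_size % 2 == 0:
        image_size += 1
    c = (image_size - 1) / 2.0
    stack = build_model_stack(config, max(0.0, z_p_values.min() - 200.0),
                              z_p_values.max() + 200.0, z_step,
                              n_bins=n_bins, r_max_px=r_max_px,
                              scatterer_strength=strength)
    rng = np.random.default_rng(seed)
    ax_std = np.full((sigma_levels.size, z_p_values.size), np.nan)
    ax_bias = np.full_like(ax_std, np.nan)
    lat_std = np.full_like(ax_std, np.nan)
    failures = 0
    px = config.pixel_size_sample
    for i, s_n in enumerate(sigma_levels):
        for j, z_p in enumerate(z_p_values):
            clean = render_frame(config, (0.0, 0.0, float(z_p)), image_size,
                                 strength)
            ax_errs, lat_errs = [], []
            for _ in range(n_realizations):
                noisy = clean + rng.normal(0.0, s_n, clean.shape)
                hit = rvt_localize(noisy, tracking.rvt_r_min,
                                   tracking.rvt_r_max, tracking.rvt_r_step,
                                   confidence_floor=0.0)
                if hit is not None:
                    lat_errs.append(np.hypot(hit[0] - c, hit[1] - c) * px)
                try:
                    z_hat = _single_frame_z(noisy, (c, c), stack, n_bins,
                                            r_max_px, tracking)
                    ax_errs.append(z_hat - z_p)
                except ValueError:
                    failures += 1
            if ax_errs:
                ax_std[i, j] = float(np.std(ax_errs))
                ax_bias[i, j] = float(np.mean(ax_errs))
            if lat_errs:
                # radial error has no sign; report its RMS as the spread
                lat_std[i, j] = float(np.sqrt(np.mean(np.square(lat_errs))))
    return ErrorStudyResult(grid_rows=sigma_levels, grid_cols=z_p_values,
                            axial_std=ax_std, axial_bias=ax_bias,
                            lateral_std=lat_std,
                            n_realizations=n_realizations,
                            n_failures=failures, seed=seed)


def lateral_offset_study(config: OpticalConfig,
                         offsets,
                         z_p_values,
                         diameter: float = 40.0,
                         r_max_px: float = 50.0,
                         z_step: float = 1.0,
                         tracking: TrackingConfig = TrackingConfig()
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean absolute axial error versus lateral-center offset, no noise.

    Radial profiles of noiseless frames are extracted about a center
    displaced by each offset (nm); the height ramp is tracked with the full
    pipeline and the absolute axial errors are averaged over the heights.
    Returns ``(offsets, mean_abs_error_nm)``.
    """
    offsets = np.asarray(offsets, dtype=float)
    z_p_values = np.asarray(z_p_values, dtype=float)
    strength = gnp_scatterer_strength(diameter, config)
    n_bins = int(r_max_px)
    margin = int(np.ceil(offsets.max() / config.pixel_size_sample)) + 1
    image_size = 2 * (int(np.ceil(r_max_px)) + margin) + 1
    c = (image_size - 1) / 2.0
    stack = build_model_stack(config, max(0.0, z_p_values.min() - 200.0),
                              z_p_values.max() + 200.0, z_step,
                              n_bins=n_bins, r_max_px=r_max_px,
                              scatterer_strength=strength)
    frames = np.stack([render_frame(config, (0.0, 0.0, float(z)), image_size,
                                    strength) for z in z_p_values])
    mean_abs = np.empty(offsets.size)
    for k, off in enumerate(offsets):
        cx = c + off / config.pixel_size_sample
        rows = []
        radii = None
        for frame in frames:
            prof = radial_profile_resampled(frame, (cx, c), n_bins, r_max_px,
                                            pixel_size=config.pixel_size_sample)
            rows.append(prof.values)
            radii = prof.radii
        series = RadialProfileSeries(frames=np.arange(z_p_values.size),
                                     radii=radii, values=np.vstack(rows))
        result = track_axial(series, stack, threshold=tracking.threshold,
                             refine_window=tracking.refine_window)
        mean_abs[k] = float(np.nanmean(np.abs(result.z_nm - z_p_values)))
    return offsets, mean_abs
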