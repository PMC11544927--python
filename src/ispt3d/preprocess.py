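"""Raw-video conversion, lateral localization and radial-profile extraction.

The chain for experimental recordings is: per-frame power normalization
(laser fluctuation removal), temporal-median background division (yielding
signed contrast), radial-variance-transform (RVT) lateral localization, and
azimuthal averaging about each frame's sub-pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from .config import OpticalConfig
from .optics import radial_average, radial_profile_resampled
from .simulate import ContrastVideo

__all__ = [
    "LateralTrack",
    "RadialProfileSeries",
    "normalize_frame_power",
    "temporal_median_background",
    "rvt_map",
    "rvt_localize",
    "extract_profiles",
]


@dataclass
class LateralTrack:
    """Per-frame sub-pixel centers; NaN marks a missed detection."""

    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frames)
        for name in ("x_px", "y_px", "confidence"):
            if len(getattr(self, name)) != n:
                raise ValueError("track arrays must share one entry per frame")

    def positions_nm(self, config: OpticalConfig,
                     image_size: int) -> np.ndarray:
        """(x, y) in nm relative to the field center."""
        c = (image_size - 1) / 2.0
        return np.column_stack(((self.x_px - c), (self.y_px - c))) \
            * config.pixel_size_sample


@dataclass
class RadialProfileSeries:
    """Frames x radii matrix of experimental radial profiles RP_e(i, r)."""

    frames: np.ndarray
    radii: np.ndarray              # nm, ascending, shared by all rows
    values: np.ndarray             # (n_frames, n_radii)
    effective_r_max: np.ndarray | None = None   # per-frame, before truncation
    dropped_frames: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.frames), len(self.radii)):
            raise ValueError("values must be (n_frames, n_radii)")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be ascending")


def normalize_frame_power(video: np.ndarray | ContrastVideo,
                          frame_interval: float | None = None,
                          pixel_size: float | None = None) -> ContrastVideo:
    """Divide each frame by its pixel sum, rescaled by the mean frame sum.

    Removes frame-to-frame illumination power fluctuations while keeping
    typical values of order the raw counts.
    """
    if isinstance(video, ContrastVideo):
        frames = video.frames
        frame_interval = video.frame_interval
        pixel_size = video.pixel_size
    else:
        frames = np.asarray(video, dtype=float)
        if frame_interval is None:
            frame_interval = 1.0
    sums = frames.sum(axis=(1, 2))
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"frame {bad[0]}: nonpositive pixel sum, cannot "
                         "normalize")
    out = frames * (sums.mean() / sums)[:, None, None]
    return ContrastVideo(frames=out, frame_interval=frame_interval,
                         provenance="normalized", pixel_size=pixel_size)


def temporal_median_background(video: ContrastVideo | np.ndarray,
                               window: int,
                               frame_interval: float | None = None,
                               pixel_size: float | None = None) -> ContrastVideo:
    """Rolling temporal-median background division yielding contrast frames.

    Per pixel, ``C_i = (F_i - med_i) / med_i`` where ``med_i`` is the median
    over ``window`` frames centered on ``i`` (truncated at the video edges).
    The median is the reference intensity level, so it must be positive
    wherever the residual is nonzero.
    """
    if isinstance(video, ContrastVideo):
        frames = np.asarray(video.frames, dtype=float)
        frame_interval = video.frame_interval
        pixel_size = video.pixel_size
    else:
        frames = np.asarray(video, dtype=float)
        if frame_interval is None:
            frame_interval = 1.0
    n = frames.shape[0]
    if window % 2 == 0 or window < 3 or window > n:
        raise ValueError("window must be odd, >= 3 and <= the frame count")
    half = window // 2
    out = np.empty_like(frames)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = np.median(frames[lo:hi], axis=0)
        residual = frames[i] - med
        nonpos = med <= 0
        if np.any(nonpos & (residual != 0)):
            raise ValueError("nonpositive temporal median: invalid reference "
                             "level (is the input raw/normalized counts?)")
        med = np.where(nonpos, 1.0, med)
        out[i] = residual / med
    return ContrastVideo(frames=out, frame_interval=frame_interval,
                         provenance="background_corrected",
                         pixel_size=pixel_size)


# --------------------------------------------------------------------------
# radial variance transform

_kernel_cache: dict[tuple, tuple] = {}


def _ring_kernels(shape: tuple[int, int], radii: tuple[int, ...],
                  width: float):
    """FFTs of normalized annulus kernels, plus pixel counts, cached."""
    key = (shape, radii, width)
    cached = _kernel_cache.get(key)
    if cached is not None:
        return cached
    r_out = radii[-1] + width / 2.0
    k = int(np.ceil(r_out))
    size = 2 * k + 1
    fshape = (spfft.next_fast_len(shape[0] + size - 1),
              spfft.next_fast_len(shape[1] + size - 1))
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    dist = np.hypot(xx, yy)
    ffts, counts = [], []
    for r in radii:
        ring = (dist >= r - width / 2.0) & (dist < r + width / 2.0)
        counts.append(int(ring.sum()))
        ffts.append(spfft.rfft2(ring.astype(float), fshape))
    out = (np.array(ffts), np.array(counts), size, fshape)
    _kernel_cache[key] = out
    return out


def rvt_map(image: np.ndarray, r_min: int, r_max: int,
            r_step: int = 1) -> np.ndarray:
    """Radial variance transform of a frame.

    For every candidate center, annular means ``mu_r`` and annular variances
    ``s2_r`` are computed over radii ``r_min..r_max`` (annulus width
    ``r_step``, pixels outside the image counted as zero), and the
    transform is ``Var_r(mu_r) - Mean_r(s2_r)``: large where concentric
    structure aligns, which is the center of a ring-shaped iPSF.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if not 0 < r_min < r_max:
        raise ValueError("need 0 < r_min < r_max")
    if r_max >= min(h, w) / 2:
        raise ValueError("r_max must be below half the image size")
    radii = tuple(range(r_min, r_max + 1, r_step))
    ffts, counts, size, fshape = _ring_kernels((h, w), radii, float(r_step))
    k = size // 2
    f_img = spfft.rfft2(image, fshape)
    f_img2 = spfft.rfft2(image * image, fshape)
    mu = np.empty((len(radii), h, w))
    q = np.empty((len(radii), h, w))
    for j in range(len(radii)):
        conv = spfft.irfft2(f_img * ffts[j], fshape)
        mu[j] = conv[k:k + h, k:k + w] / counts[j]
        conv2 = spfft.irfft2(f_img2 * ffts[j], fshape)
        q[j] = conv2[k:k + h, k:k + w] / counts[j]
    var_of_means = mu.var(axis=0)
    mean_of_vars = (q - mu * mu).mean(axis=0)
    return var_of_means - mean_of_vars


def rvt_localize(frame: np.ndarray, r_min: int, r_max: int,
                 r_step: int = 1,
                 confidence_floor: float = 0.3
                 ) -> tuple[float, float, float] | None:
    """Sub-pixel center of the radially symmetric pattern in a frame.

    Returns ``(x, y, confidence)`` with the transform's peak refined by
    quadratic interpolation of its 3x3 neighbourhood.  Confidence is the
    ratio of the peak to the largest transform magnitude far from it
    (beyond ``r_max``): a ring-shaped iPSF produces a strongly positive,
    isolated peak while a noise-only transform is weak and sign-mixed, so
    the ratio is near 1 without a particle.  ``None`` signals no detection
    above the floor (frame flagged by the caller, not fatal).
    """
    t = rvt_map(frame, r_min, r_max, r_step)
    iy, ix = np.unravel_index(int(np.argmax(t)), t.shape)
    yy, xx = np.mgrid[0:t.shape[0], 0:t.shape[1]]
    far = t[np.hypot(xx - ix, yy - iy) > r_max + 1]
    scale = float(np.max(np.abs(far))) if far.size else 0.0
    confidence = float(t[iy, ix] / scale) if scale > 0 else np.inf
    if confidence < confidence_floor or t[iy, ix] <= 0:
        return None
    x, y = float(ix), float(iy)
    if 0 < ix < t.shape[1] - 1 and 0 < iy < t.shape[0] - 1:
        for axis, (m, c, p) in (("x", (t[iy, ix - 1], t[iy, ix], t[iy, ix + 1])),
                                ("y", (t[iy - 1, ix], t[iy, ix], t[iy + 1, ix]))):
            denom = m - 2 * c + p
            if denom < 0:
                delta = 0.5 * (m - p) / denom
                if axis == "x":
                    x += delta
                else:
                    y += delta
    return x, y, confidence


def intensity_peak_localize(frame: np.ndarray,
                            z_floor: float = 10.0
                            ) -> tuple[float, float, float] | None:
    """Sub-pixel |contrast| peak with 3x3 quadratic refinement.

    The radial variance transform needs resolvable ring structure and can
    fail within a few hundred nm of the focal plane, where the iPSF
    collapses into a compact bright (or dark) spot; there, the smoothed
    |C| peak is an excellent center estimate.  Confidence is the peak's
    z-score over the frame (noise-only frames stay below ~5).
    """
    from scipy.ndimage import gaussian_filter
    mag = gaussian_filter(np.abs(np.asarray(frame, dtype=float)), 1.0)
    iy, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    std = mag.std()
    z_score = (mag[iy, ix] - mag.mean()) / std if std > 0 else 0.0
    if z_score < z_floor:
        return None
    x, y = float(ix), float(iy)
    if 0 < ix < mag.shape[1] - 1 and 0 < iy < mag.shape[0] - 1:
        dx = mag[iy, ix - 1] - 2 * mag[iy, ix] + mag[iy, ix + 1]
        dy = mag[iy - 1, ix] - 2 * mag[iy, ix] + mag[iy + 1, ix]
        if dx < 0:
            x += 0.5 * (mag[iy, ix - 1] - mag[iy, ix + 1]) / dx
        if dy < 0:
            y += 0.5 * (mag[iy - 1, ix] - mag[iy + 1, ix]) / dy
    return x, y, float(z_score)


def localize_video(video: ContrastVideo, r_min: int, r_max: int,
                   r_step: int = 1, confidence_floor: float = 0.3,
                   roi_half: int | None = None) -> LateralTrack:
    """RVT localization of every frame, optionally in a tracking ROI.

    With ``roi_half`` set, each frame is searched only within a box of that
    half-size around the previous frame's center (falling back to the full
    frame when there is no previous detection), which speeds up long videos
    of a single slowly wandering particle.
    """
    n = video.n_frames
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    conf = np.zeros(n)
    prev: tuple[float, float] | None = None
    for i in range(n):
        frame = video.frames[i]
        ox = oy = 0
        if roi_half is not None and prev is not None:
            cx, cy = int(round(prev[0])), int(round(prev[1]))
            ox = max(0, min(cx - roi_half, frame.shape[1] - 2 * roi_half - 1))
            oy = max(0, min(cy - roi_half, frame.shape[0] - 2 * roi_half - 1))
            frame = frame[oy:oy + 2 * roi_half + 1, ox:ox + 2 * roi_half + 1]
        hit = rvt_localize(frame, r_min, r_max, r_step, confidence_floor)
        if hit is None and (ox or oy or frame.shape != video.frames[i].shape):
            # particle may have left the ROI: fall back to the full frame
            ox = oy = 0
            hit = rvt_localize(video.frames[i], r_min, r_max, r_step,
                               confidence_floor)
        if hit is None:
            # near focus the iPSF loses its rings; use the |C| peak instead
            hit = intensity_peak_localize(video.frames[i])
        if hit is not None:
            x[i], y[i], conf[i] = hit[0] + ox, hit[1] + oy, hit[2]
            prev = (x[i], y[i])
        else:
            prev = None
    return LateralTrack(frames=np.arange(n), x_px=x, y_px=y, confidence=conf)


def _fill_gaps(values: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation over NaN gaps up to ``max_gap``; longer gaps stay."""
    out = values.copy()
    isnan = np.isnan(values)
    if not isnan.any():
        return out, np.array([], int)
    idx = np.arange(values.size)
    good = ~isnan
    if good.sum() < 2:
        return out, idx[isnan]
    filled = np.interp(idx, idx[good], values[good])
    dropped = []
    i = 0
    while i < values.size:
        if isnan[i]:
            j = i
            while j < values.size and isnan[j]:
                j += 1
            if (j - i) <= max_gap and i > 0 and j < values.size:
                out[i:j] = filled[i:j]
            else:
                dropped.extend(range(i, j))
            i = j
        else:
            i += 1
    return out, np.array(dropped, int)


def extract_profiles(video: ContrastVideo,
                     track: LateralTrack,
                     n_bins: int,
                     r_max: float,
                     config: OpticalConfig | None = None,
                     max_gap: int = 5) -> RadialProfileSeries:
    """Azimuthal average of every frame about its sub-pixel center.

    Missing detections are bridged by linear center interpolation across
    gaps of at most ``max_gap`` frames; frames in longer gaps are dropped
    (recorded).  Centers too close to an edge reduce that frame's usable
    radius; all rows are then truncated to the common radial grid.
    """
    pixel_size = (config.pixel_size_sample if config is not None
                  else video.pixel_size) or 1.0
    x, dropped_x = _fill_gaps(np.asarray(track.x_px, float), max_gap)
    y, dropped_y = _fill_gaps(np.asarray(track.y_px, float), max_gap)
    dropped = np.union1d(dropped_x, dropped_y)
    keep = np.setdiff1d(np.arange(video.n_frames), dropped)
    if keep.size == 0:
        raise ValueError("no frames with a usable center")
    h, w = video.frames.shape[1:]
    width = r_max / n_bins
    eff_r = np.minimum(r_max, np.minimum.reduce(
        [x[keep] + 0.5, y[keep] + 0.5, w - 0.5 - x[keep], h - 0.5 - y[keep]]))
    common_bins = int(np.floor(eff_r.min() / width))
    if common_bins < 2:
        raise ValueError("centers too close to the edge for a usable profile")
    rows = np.empty((keep.size, common_bins))
    radii = None
    for k, i in enumerate(keep):
        prof = radial_profile_resampled(video.frames[i], (x[i], y[i]),
                                        common_bins, common_bins * width,
                                        pixel_size=pixel_size)
        rows[k] = prof.values
        radii = prof.radii
    return RadialProfileSeries(frames=keep, radii=radii, values=rows,
                               effective_r_max=eff_r,
                               dropped_frames=dropped.astype(int))
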