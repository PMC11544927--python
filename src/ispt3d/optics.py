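"""Interferometric point-spread-function (iPSF) model.

A Rayleigh scatterer at height ``z_p`` above the coverslip is imaged through
the stratified water / glass / immersion-oil sequence of a high-NA objective.
The detected signal is the interference of the field scattered by the
particle with the reference field reflected at the water-glass interface,

    I_det = |E_ref|^2 + |E_sca|^2 + 2 |E_ref||E_sca| cos(phi),

and images are expressed as the contrast ``C = (I_det - I_ref) / I_ref``.

The scattered field is computed as a scalar angular-spectrum (pupil)
integral: amplitude apodization ``sqrt(cos theta)`` for an aplanatic
objective, s-polarization Fresnel transmission at the two interfaces, a
defocus phase referenced to the focal plane ``z_f``, an illumination phase
``k n_m z_p`` for the upward pass, and a Gibson-Lanni-style aberration phase
from the mismatch between the actual and design glass/oil parameters.  The
mismatch term breaks the mirror symmetry of the iPSF about the focal plane,
which is what lets the tracker tell above-focus from below-focus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import j0

from .config import GOLD_EPSILON_515, OpticalConfig

__all__ = [
    "FieldAmplitudes",
    "ContrastImage",
    "RadialProfile",
    "RadialModelStack",
    "CalibrationResult",
    "ipsf_contrast",
    "interface_reflectivity",
    "gnp_scatterer_strength",
    "scattered_field_radial",
    "contrast_profile",
    "compute_ipsf_image",
    "radial_average",
    "radial_profile_resampled",
    "build_model_stack",
    "stack_pearson",
    "calibrate_model",
    "save_stack",
    "load_stack",
]



@dataclass(frozen=True)
class FieldAmplitudes:
    """Reference/scattered field amplitudes relative to the incident field."""

    ref_amplitude: float
    sca_amplitude: float
    phase_diff: float  # rad

    def __post_init__(self) -> None:
        if self.ref_amplitude < 0 or self.sca_amplitude < 0:
            raise ValueError("field amplitudes must be nonnegative")


@dataclass
class ContrastImage:
    """Signed contrast image of a scatterer; ``C >= -1`` everywhere."""

    pixels: np.ndarray
    center_estimate: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("contrast image contains non-finite values")
        if np.any(self.pixels < -1.0 - 1e-9):
            raise ValueError("contrast below -1 implies negative intensity")


@dataclass
class RadialProfile:
    """Azimuthally averaged contrast versus distance from the iPSF center."""

    radii: np.ndarray   # ascending, nm (or px if no pixel size was supplied)
    values: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape:
            raise ValueError("radii and values must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class RadialModelStack:
    """Modelled radial iPSF profiles RP_m(z, r) on a uniform axial grid.

    ``scan='particle'`` varies the particle height ``z_p`` at fixed focal
    plane (the tracking model); ``scan='focus'`` varies the focal plane at
    fixed particle height (the calibration measurement geometry).
    """

    z_grid: np.ndarray        # nm
    radii: np.ndarray         # nm
    profiles: np.ndarray      # (len(z_grid), len(radii))
    z_step: float
    config: OpticalConfig
    scan: str = "particle"
    scatterer_strength: complex = 0.0

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape[0] != self.z_grid.size:
            raise ValueError("profiles row count must match z_grid length")
        dz = np.diff(self.z_grid)
        if self.z_grid.size > 1 and (np.any(dz <= 0) or not np.allclose(dz, dz[0])):
            raise ValueError("z_grid must be ascending and uniform")

    def row_at(self, z: float) -> np.ndarray:
        """Profile at arbitrary z by linear interpolation between grid rows."""
        if not self.z_grid[0] <= z <= self.z_grid[-1]:
            raise ValueError(f"z={z} nm outside model stack range "
                             f"[{self.z_grid[0]}, {self.z_grid[-1]}] nm")
        i = min(int((z - self.z_grid[0]) // self.z_step), self.z_grid.size - 2) \
            if self.z_grid.size > 1 else 0
        if self.z_grid.size == 1:
            return self.profiles[0]
        frac = (z - self.z_grid[i]) / self.z_step
        return (1 - frac) * self.profiles[i] + frac * self.profiles[i + 1]


# --------------------------------------------------------------------------
# elementary contrast relation

def ipsf_contrast(amps: FieldAmplitudes) -> float:
    """Contrast ``(I_det - I_ref)/I_ref = (s^2 + 2 r s cos phi) / r^2``."""
    r, s = amps.ref_amplitude, amps.sca_amplitude
    if r == 0:
        raise ZeroDivisionError("no reference field: contrast undefined")
    return (s * s + 2.0 * r * s * np.cos(amps.phase_diff)) / (r * r)


def interface_reflectivity(config: OpticalConfig) -> float:
    """Normal-incidence field reflectivity of the glass-water interface.

    Seen from the glass side (illumination through the objective), so the
    reflected reference keeps the sign of ``n_glass - n_medium``.
    """
    return (config.n_glass - config.n_medium) / (config.n_glass + config.n_medium)


def gnp_scatterer_strength(diameter: float,
                           config: OpticalConfig,
                           epsilon_particle: complex = GOLD_EPSILON_515) -> complex:
    """Scattered-field amplitude prefactor of a Rayleigh gold sphere.

    ``s = k_m^3 (d/2)^3 (eps-eps_m)/(eps+2 eps_m)`` -- the angular-spectrum
    prefactor of a point dipole whose image-plane field is this factor times
    the (physically normalized) pupil integral.  An ideally transmitting
    aplanatic system collecting the full water-side half space reimages a
    peak field of about ``s (1 - cos theta_max)``; interface transmission
    and apodization losses are carried inside the pupil integral itself.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    eps_m = config.n_medium ** 2
    k_m = config.k_vacuum * config.n_medium
    lorentz = (epsilon_particle - eps_m) / (epsilon_particle + 2 * eps_m)
    return (k_m ** 3) * (diameter / 2.0) ** 3 * lorentz


# --------------------------------------------------------------------------
# pupil machinery

_pupil_cache: dict[OpticalConfig, tuple] = {}


def _pupil(config: OpticalConfig):
    """Quadrature nodes over the collection pupil plus fixed phase factors.

    Returns ``(s_nodes, amplitudes, cos_m, w_ab, norm)`` where ``s`` is the
    conserved transverse direction sine ``n sin(theta)``, ``amplitudes``
    combine quadrature weight, apodization and Fresnel transmissions,
    ``cos_m`` is ``cos(theta)`` in the sample medium and ``w_ab`` the static
    stratified-media aberration phase (rad).
    """
    cached = _pupil_cache.get(config)
    if cached is not None:
        return cached
    if config.numerical_aperture >= config.n_oil:
        raise ValueError("numerical aperture must be below the oil index")
    n_m, n_g, n_o = config.n_medium, config.n_glass, config.n_oil
    # Only directions that propagate in every layer carry scattered light.
    s_max = min(config.numerical_aperture, n_m, n_g, n_o) * (1.0 - 1e-9)
    x, w = np.polynomial.legendre.leggauss(config.n_pupil_samples)
    s = 0.5 * s_max * (x + 1.0)
    ws = 0.5 * s_max * w
    cos_m = np.sqrt(n_m ** 2 - s ** 2) / n_m
    cos_g = np.sqrt(n_g ** 2 - s ** 2) / n_g
    cos_o = np.sqrt(n_o ** 2 - s ** 2) / n_o
    # s-polarization Fresnel transmission, water->glass->oil.
    t_wg = 2 * n_m * cos_m / (n_m * cos_m + n_g * cos_g)
    t_go = 2 * n_g * cos_g / (n_g * cos_g + n_o * cos_o)
    # Solid-angle measure sin(theta_m) d theta_m expressed in s = n sin(theta):
    # s ds / (n_m^2 cos theta_m); the grazing divergence cancels against t_wg.
    amp = (ws * s / (n_m ** 2 * cos_m)
           * np.sqrt(np.clip(cos_o, 0, None)) * t_wg * t_go)
    k0 = config.k_vacuum
    # Gibson-Lanni mismatch between actual and design glass/oil columns.
    w_ab = k0 * (
        config.t_glass * np.sqrt(n_g ** 2 - s ** 2)
        - config.design_t_glass * np.sqrt(config.design_n_glass ** 2 - s ** 2)
        + config.t_oil * np.sqrt(n_o ** 2 - s ** 2)
        - config.design_t_oil * np.sqrt(config.design_n_oil ** 2 - s ** 2)
    )
    # Remove piston and the best-fit defocus component: the focal plane is
    # defined operationally (the user focuses the microscope), so only the
    # higher-order part of the mismatch phase survives as true spherical
    # aberration.  Amplitude-weighted least squares onto {1, cos theta_m}.
    basis = np.vstack([np.ones_like(cos_m), cos_m]).T
    sw = np.sqrt(np.abs(amp))
    coef, *_ = np.linalg.lstsq(basis * sw[:, None], w_ab * sw, rcond=None)
    w_ab = w_ab - basis @ coef
    norm = 1.0  # physical normalization: field = strength * integral
    out = (s, amp, cos_m, w_ab, norm)
    _pupil_cache[config] = out
    return out


def scattered_field_radial(config: OpticalConfig,
                           particle_z: float,
                           radii: np.ndarray,
                           j0_matrix: np.ndarray | None = None) -> np.ndarray:
    """Complex scattered field (unit scatterer strength) at radial offsets.

    ``radii`` are distances from the particle's lateral position, nm.  The
    result is normalized so a perfectly focused, aberration-free field peaks
    at 1; multiply by the (complex) scatterer strength to get physical units.
    """
    if particle_z < 0:
        raise ValueError("particle must sit above the coverslip (z_p >= 0)")
    s, amp, cos_m, w_ab, norm = _pupil(config)
    k0 = config.k_vacuum
    n_m = config.n_medium
    phase = (k0 * n_m * particle_z
             + k0 * n_m * cos_m * (particle_z - config.focal_plane_z)
             + w_ab)
    weights = amp * np.exp(1j * phase)
    if j0_matrix is None:
        j0_matrix = j0(np.multiply.outer(np.asarray(radii, float), k0 * s))
    return j0_matrix @ weights / norm


def contrast_profile(config: OpticalConfig,
                     particle_z: float,
                     radii: np.ndarray,
                     scatterer_strength: complex,
                     j0_matrix: np.ndarray | None = None) -> np.ndarray:
    """Radial contrast ``C(r)`` of the iPSF for a particle at ``particle_z``."""
    field = scatterer_strength * scattered_field_radial(
        config, particle_z, radii, j0_matrix)
    ref = interface_reflectivity(config) * np.exp(1j * config.reference_phase)
    return (np.abs(ref + field) ** 2 - np.abs(ref) ** 2) / np.abs(ref) ** 2


class RadialFieldEvaluator:
    """Reusable evaluator caching the Bessel matrix for a fixed radial grid.

    Building a model stack or rendering a long video evaluates the pupil
    integral at thousands of heights over the same radii; precomputing
    ``J0(k s r)`` makes each height a single matrix-vector product.
    """

    def __init__(self, config: OpticalConfig, radii: np.ndarray):
        self.config = config
        self.radii = np.asarray(radii, dtype=float)
        s, *_ = _pupil(config)
        self._j0 = j0(np.multiply.outer(self.radii, config.k_vacuum * s))

    def field(self, particle_z: float) -> np.ndarray:
        return scattered_field_radial(self.config, particle_z, self.radii,
                                      self._j0)

    def contrast(self, particle_z: float, scatterer_strength: complex) -> np.ndarray:
        return contrast_profile(self.config, particle_z, self.radii,
                                scatterer_strength, self._j0)


_evaluator_cache: dict[tuple, RadialFieldEvaluator] = {}


def _fine_evaluator(config: OpticalConfig, r_needed: float) -> RadialFieldEvaluator:
    """Evaluator on a fine radial grid covering ``[0, r_needed]`` nm."""
    step = config.pixel_size_sample / 4.0
    n = int(np.ceil(r_needed / step)) + 2
    key = (config, round(step, 9), n)
    ev = _evaluator_cache.get(key)
    if ev is None:
        ev = RadialFieldEvaluator(config, np.arange(n) * step)
        _evaluator_cache[key] = ev
    return ev


def compute_ipsf_image(config: OpticalConfig,
                       particle_z: float,
                       lateral_offset: tuple[float, float] = (0.0, 0.0),
                       scatterer_strength: complex = 0.01,
                       image_size: int = 101) -> ContrastImage:
    """Render the circularly symmetric contrast image of a point scatterer.

    ``lateral_offset`` displaces the particle from the center pixel, nm.
    The field is evaluated on a fine radial grid (quarter-pixel sampling)
    and interpolated onto the pixel raster, which preserves the model's
    exact circular symmetry about the particle position.
    """
    if image_size % 2 != 1:
        raise ValueError("image_size must be odd so a center pixel exists")
    if particle_z < 0:
        raise ValueError("particle_z must be nonnegative")
    px = config.pixel_size_sample
    c = image_size // 2
    cx = c + lateral_offset[0] / px
    cy = c + lateral_offset[1] / px
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dist = np.hypot(xx - cx, yy - cy) * px
    ev = _fine_evaluator(config, float(dist.max()))
    profile = ev.contrast(particle_z, scatterer_strength)
    pixels = np.interp(dist.ravel(), ev.radii, profile).reshape(dist.shape)
    return ContrastImage(pixels=pixels, center_estimate=(cx, cy))


# --------------------------------------------------------------------------
# radial averaging

def radial_average(image: ContrastImage | np.ndarray,
                   center: tuple[float, float],
                   n_bins: int,
                   r_max: float,
                   pixel_size: float | None = None) -> RadialProfile:
    """Azimuthal mean of an image over annular bins about a sub-pixel center.

    ``center`` and ``r_max`` are in pixels.  Bin ``k`` collects pixels whose
    center distance falls in ``[k*d, (k+1)*d)`` with ``d = r_max/n_bins``;
    empty bins are filled by linear interpolation from their neighbours.
    Radii are reported at bin centers, scaled to nm when ``pixel_size`` is
    given.
    """
    pixels = image.pixels if isinstance(image, ContrastImage) else np.asarray(image, float)
    h, w = pixels.shape
    cx, cy = center
    if not (-0.5 <= cx <= w - 0.5 and -0.5 <= cy <= h - 0.5):
        raise ValueError("center must lie inside the image")
    edge = min(cx + 0.5, cy + 0.5, w - 0.5 - cx, h - 0.5 - cy)
    if r_max > edge + 1e-9:
        raise ValueError(f"r_max={r_max} px exceeds distance {edge:.2f} px "
                         "to the nearest image edge")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    width = r_max / n_bins
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy).ravel()
    idx = np.floor(dist / width).astype(np.intp)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=pixels.ravel()[keep], minlength=n_bins)
    values = np.full(n_bins, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    if not nz.all():
        if not nz.any():
            raise ValueError("all radial bins empty")
        values = np.interp(np.arange(n_bins), np.flatnonzero(nz), values[nz])
    radii = (np.arange(n_bins) + 0.5) * width
    if pixel_size is not None:
        radii = radii * pixel_size
    return RadialProfile(radii=radii, values=values)


def radial_profile_resampled(image: ContrastImage | np.ndarray,
                             center: tuple[float, float],
                             n_bins: int,
                             r_max: float,
                             pixel_size: float | None = None) -> RadialProfile:
    """Azimuthal average resampled onto the canonical bin-center radii.

    Raw annular bin means are samples of the profile at each bin's *mean
    pixel distance*, which shifts with the sub-pixel center; comparing raw
    means from different centers therefore carries a systematic distortion
    (several nm of axial bias through the correlation).  Interpolating the
    means from their actual mean radii onto the fixed bin-center grid makes
    profiles from any sub-pixel center directly comparable, so both the
    model stack and the per-frame extraction use this form.
    """
    pixels = image.pixels if isinstance(image, ContrastImage) else np.asarray(image, float)
    raw = radial_average(pixels, center, n_bins, r_max)
    h, w = pixels.shape
    cx, cy = center
    width = r_max / n_bins
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy).ravel()
    idx = np.floor(dist / width).astype(np.intp)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins).astype(float)
    rsum = np.bincount(idx[keep], weights=dist[keep], minlength=n_bins)
    nz = counts > 0
    mean_r = np.where(nz, rsum / np.maximum(counts, 1), raw.radii)
    order = np.argsort(mean_r)
    values = np.interp(raw.radii, mean_r[order], raw.values[order])
    radii = raw.radii * pixel_size if pixel_size is not None else raw.radii
    return RadialProfile(radii=radii, values=values)


# --------------------------------------------------------------------------
# model stacks

_stack_cache: dict[tuple, RadialModelStack] = {}


def build_model_stack(config: OpticalConfig,
                      z_min: float,
                      z_max: float,
                      z_step: float,
                      n_bins: int = 50,
                      r_max_px: float = 50.0,
                      scatterer_strength: complex | None = None,
                      scan: str = "particle",
                      particle_z: float = 20.0,
                      image_size: int | None = None,
                      cache: bool = True) -> RadialModelStack:
    """Model radial profiles on a uniform axial grid.

    Each row is produced by rendering the on-axis iPSF image and azimuthally
    averaging it, exactly the operation applied to data frames.  With
    ``scan='particle'`` the grid is the particle height ``z_p``; with
    ``scan='focus'`` it is the focal-plane position ``z_f`` with the
    particle resting on the glass at ``particle_z`` (its radius), which is
    the calibration-measurement geometry.
    """
    if z_min >= z_max:
        raise ValueError("z_min must be below z_max")
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    if scan not in ("particle", "focus"):
        raise ValueError("scan must be 'particle' or 'focus'")
    if scatterer_strength is None:
        scatterer_strength = gnp_scatterer_strength(40.0, config)
    if image_size is None:
        image_size = 2 * int(np.ceil(r_max_px)) + 1
    key = (config, z_min, z_max, z_step, n_bins, r_max_px,
           complex(scatterer_strength), scan, particle_z, image_size)
    if cache and key in _stack_cache:
        return _stack_cache[key]
    n_z = int(round((z_max - z_min) / z_step)) + 1
    z_grid = z_min + z_step * np.arange(n_z)
    center = (image_size // 2, image_size // 2)
    profiles = np.empty((n_z, n_bins))
    radii = None
    for i, z in enumerate(z_grid):
        if scan == "particle":
            img = compute_ipsf_image(config, z, (0.0, 0.0),
                                     scatterer_strength, image_size)
        else:
            img = compute_ipsf_image(config.replace(focal_plane_z=float(z)),
                                     particle_z, (0.0, 0.0),
                                     scatterer_strength, image_size)
        prof = radial_profile_resampled(img, center, n_bins, r_max_px,
                                        pixel_size=config.pixel_size_sample)
        profiles[i] = prof.values
        radii = prof.radii
    stack = RadialModelStack(z_grid=z_grid, radii=radii, profiles=profiles,
                             z_step=z_step, config=config, scan=scan,
                             scatterer_strength=complex(scatterer_strength))
    if cache:
        _stack_cache[key] = stack
    return stack


def stack_pearson(stack_a, stack_b) -> float:
    """Global Pearson correlation between two equally shaped profile stacks."""
    a = np.asarray(stack_a.profiles if isinstance(stack_a, RadialModelStack)
                   else stack_a, float).ravel()
    b = np.asarray(stack_b.profiles if isinstance(stack_b, RadialModelStack)
                   else stack_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("stacks must have identical shapes")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("undefined correlation: a stack has zero variance")
    return float((a @ b) / denom)


@dataclass
class CalibrationResult:
    """Outcome of the (n_g, n_o, t_g) focal-stack calibration."""

    n_glass: float
    n_oil: float
    t_glass: float
    correlation: float
    surface: np.ndarray          # (len(ng), len(no), len(tg)), NaN = invalid
    n_glass_grid: np.ndarray
    n_oil_grid: np.ndarray
    t_glass_grid: np.ndarray


def calibrate_model(measured_stack: RadialModelStack,
                    n_glass_grid: Sequence[float],
                    n_oil_grid: Sequence[float],
                    t_glass_grid: Sequence[float],
                    config: OpticalConfig,
                    particle_z: float = 20.0,
                    scatterer_strength: complex | None = None) -> CalibrationResult:
    """Maximize the stack Pearson correlation over (n_g, n_o, t_g).

    ``measured_stack`` must be a focal scan (profiles versus ``z_f``).  For
    every grid point, a model focal stack with identical grid and radii is
    built and correlated globally against the measurement; invalid optics at
    a grid point are skipped with a warning.  The correlation surface
    typically shows a diagonal ridge in (n_g, n_o): an index increase in the
    glass can be compensated by the oil because the summed accumulated phase
    is what matters.
    """
    ng = np.asarray(list(n_glass_grid), float)
    no = np.asarray(list(n_oil_grid), float)
    tg = np.asarray(list(t_glass_grid), float)
    if ng.size == 0 or no.size == 0 or tg.size == 0:
        raise ValueError("calibration grids must be nonempty")
    if measured_stack.scan != "focus":
        raise ValueError("calibration expects a focal-scan stack")
    z = measured_stack.z_grid
    n_bins = measured_stack.profiles.shape[1]
    r_max_px = (measured_stack.radii[-1] + measured_stack.radii[0]) \
        / measured_stack.config.pixel_size_sample
    surface = np.full((ng.size, no.size, tg.size), np.nan)
    best = (-np.inf, None)
    for i, g in enumerate(ng):
        for k, o in enumerate(no):
            for m, t in enumerate(tg):
                try:
                    trial = config.replace(n_glass=float(g), n_oil=float(o),
                                           t_glass=float(t))
                    model = build_model_stack(
                        trial, z[0], z[-1], measured_stack.z_step,
                        n_bins=n_bins, r_max_px=r_max_px,
                        scatterer_strength=scatterer_strength,
                        scan="focus", particle_z=particle_z)
                    rho = stack_pearson(measured_stack, model)
                except ValueError as err:
                    warnings.warn(f"calibration grid point (n_g={g}, n_o={o}, "
                                  f"t_g={t}) skipped: {err}")
                    continue
                surface[i, k, m] = rho
                if rho > best[0]:
                    best = (rho, (float(g), float(o), float(t)))
    if best[1] is None:
        raise ValueError("no valid calibration grid point")
    (g, o, t) = best[1]
    return CalibrationResult(n_glass=g, n_oil=o, t_glass=t,
                             correlation=best[0], surface=surface,
                             n_glass_grid=ng, n_oil_grid=no, t_glass_grid=tg)


# --------------------------------------------------------------------------
# persistence

def save_stack(stack: RadialModelStack, path: str | Path) -> None:
    """Archive a model stack (NPZ: grids, profiles, config hash + repr)."""
    np.savez_compressed(
        Path(path),
        z_grid=stack.z_grid, radii=stack.radii, profiles=stack.profiles,
        z_step=np.array(stack.z_step),
        scan=np.array(stack.scan),
        scatterer_strength=np.array(stack.scatterer_strength, dtype=complex),
        config_hash=np.array(stack.config.content_hash()),
        config_repr=np.array(repr(stack.config)),
    )


def load_stack(path: str | Path, config: OpticalConfig | None = None) -> RadialModelStack:
    """Load an archived model stack; verifies the config hash when given."""
    with np.load(Path(path), allow_pickle=False) as npz:
        stored_hash = str(npz["config_hash"])
        if config is not None and config.content_hash() != stored_hash:
            raise ValueError("model stack was built with a different optical "
                             "configuration (hash mismatch)")
        return RadialModelStack(
            z_grid=npz["z_grid"], radii=npz["radii"], profiles=npz["profiles"],
            z_step=float(npz["z_step"]), config=config or OpticalConfig(),
            scan=str(npz["scan"]),
            scatterer_strength=complex(npz["scatterer_strength"]),
        )
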