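"""Optical, camera and tracking configuration.

All lengths are nanometers and all times seconds unless a field name carries
an explicit unit suffix.  The axial origin sits at the water-glass interface,
with ``z`` increasing into the sample medium; the focal-plane position ``z_f``
is signed in the same frame (negative values place the nominal focus inside
the glass).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

try:  # Python >= 3.11
    import tomllib
except ImportError:  # pragma: no cover
    tomllib = None

__all__ = [
    "OpticalConfig",
    "CameraConfig",
    "TrackingConfig",
    "RunConfig",
    "GOLD_EPSILON_515",
    "WATER_VISCOSITY_PA_S",
    "ROOM_TEMPERATURE_K",
    "load_config",
    "dump_config",
]

#: Dielectric function of gold near 515 nm (Johnson & Christy interpolation).
GOLD_EPSILON_515: complex = -3.95 + 2.58j

#: Viscosity of water at 23.85 C (297 K), Pa*s.
WATER_VISCOSITY_PA_S: float = 0.911e-3

#: Default sample temperature, K.
ROOM_TEMPERATURE_K: float = 297.0


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the interferometric imaging system and sample stack.

    The defaults describe a high-NA oil-immersion wide-field iSCAT setup:
    515 nm illumination, a 128 px field mapping to 13 um at the sample, a
    170 um coverslip, and the calibrated glass/oil refractive indices.
    """

    wavelength_vacuum: float = 515.0          # nm
    numerical_aperture: float = 1.4
    n_medium: float = 1.33                    # water
    n_glass: float = 1.52696                  # calibrated coverslip index
    n_oil: float = 1.51833                    # calibrated immersion-oil index
    t_glass: float = 170_000.0                # nm
    t_oil: float = 150_000.0                  # effective oil column, nm
    design_n_glass: float = 1.5230            # objective design values
    design_n_oil: float = 1.5180
    design_t_glass: float = 170_000.0
    design_t_oil: float = 150_000.0
    pixel_size_sample: float = 13_000.0 / 128.0   # nm / px
    focal_plane_z: float = 3_200.0            # z_f, nm, signed
    n_pupil_samples: int = 256                # Gauss-Legendre nodes
    reference_phase: float = 0.0              # extra ref-arm phase, rad

    def __post_init__(self) -> None:
        if self.wavelength_vacuum <= 0:
            raise ValueError("wavelength_vacuum must be positive")
        if not 0 < self.numerical_aperture < self.n_oil:
            raise ValueError(
                "numerical_aperture must lie in (0, n_oil); "
                f"got NA={self.numerical_aperture}, n_oil={self.n_oil}"
            )
        for name in ("n_medium", "n_glass", "n_oil", "design_n_glass", "design_n_oil"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must exceed 1 (condensed media)")
        if self.pixel_size_sample <= 0:
            raise ValueError("pixel_size_sample must be positive")
        if self.n_pupil_samples < 8:
            raise ValueError("n_pupil_samples too small for the pupil integral")

    @property
    def k_vacuum(self) -> float:
        """Vacuum wavenumber, rad/nm."""
        return 2.0 * 3.141592653589793 / self.wavelength_vacuum

    @property
    def carrier_period(self) -> float:
        """Axial oscillation period of the interferometric phase, nm.

        A particle moving away from the interface modulates the contrast with
        period lambda / (2 n_medium) because the round-trip optical path grows
        at twice the medium wavelength rate.
        """
        return self.wavelength_vacuum / (2.0 * self.n_medium)

    def replace(self, **changes: Any) -> "OpticalConfig":
        return dataclasses.replace(self, **changes)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CameraConfig:
    """High-speed camera model: shot noise follows from the electron well."""

    full_well: float = 23_200.0     # electrons at saturation
    frame_rate: float = 100_000.0   # Hz
    exposure: float = 10e-6         # s
    background_fill: float = 1.0    # fraction of the well used by the reference

    def __post_init__(self) -> None:
        if self.full_well <= 0:
            raise ValueError("full_well must be positive")
        if not 0 < self.background_fill <= 1:
            raise ValueError("background_fill must lie in (0, 1]")
        if self.exposure > 1.0 / self.frame_rate + 1e-15:
            raise ValueError("exposure cannot exceed the frame interval")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    def replace(self, **changes: Any) -> "CameraConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TrackingConfig:
    """Knobs of the axial localization pipeline."""

    z_min: float = 0.0            # model z-grid, nm
    z_max: float = 6_000.0
    z_step: float = 1.0
    r_max_px: float = 50.0        # radial-profile extent, px
    n_radial_bins: int = 50
    rvt_r_min: int = 2            # radial-variance-transform radii, px
    rvt_r_max: int = 24
    rvt_r_step: int = 1
    threshold: float = 0.0        # correlation-map binarization threshold
    refine_window: int = 3        # grid points around the branch peak
    seed: int = 0

    def replace(self, **changes: Any) -> "TrackingConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class RunConfig:
    """Bundle of everything a pipeline run needs, loadable from TOML/YAML."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "optics": dataclasses.asdict(self.optics),
            "camera": dataclasses.asdict(self.camera),
            "tracking": dataclasses.asdict(self.tracking),
            "paths": dict(self.paths),
        }


_UM_FIELDS = {"t_glass", "t_oil", "design_t_glass", "design_t_oil",
              "focal_plane_z", "z_min", "z_max"}


def _convert_units(section: dict[str, Any]) -> dict[str, Any]:
    """Resolve ``*_um`` suffixed keys to the canonical nm fields."""
    out: dict[str, Any] = {}
    for key, value in section.items():
        if key.endswith("_um"):
            base = key[:-3]
            out[base] = float(value) * 1_000.0
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> RunConfig:
    """Read a structured TOML or YAML run configuration.

    Sections ``[optics]``, ``[camera]``, ``[tracking]`` and ``[paths]`` are
    all optional; lengths are nm unless the key carries a ``_um`` suffix.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".toml", ".tml"}:
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("TOML support requires Python >= 3.11")
        raw = tomllib.loads(text)
    else:
        raw = yaml.safe_load(text) or {}
    optics = OpticalConfig(**_convert_units(raw.get("optics", {})))
    camera = CameraConfig(**raw.get("camera", {}))
    tracking = TrackingConfig(**_convert_units(raw.get("tracking", {})))
    paths = {str(k): str(v) for k, v in raw.get("paths", {}).items()}
    return RunConfig(optics=optics, camera=camera, tracking=tracking, paths=paths)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration next to run outputs (YAML)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
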