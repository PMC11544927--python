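"""Shared fixtures: a default optical configuration and cached model stacks.

Model stacks are the expensive ingredient (thousands of pupil-integral
renders); session scope plus the library's own in-memory cache keeps the
suite inside a desk-scale time budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from ispt3d import (CameraConfig, OpticalConfig, TrackingConfig,
                    build_model_stack, gnp_scatterer_strength)


@pytest.fixture(scope="session")
def optics_config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def camera_config() -> CameraConfig:
    return CameraConfig()


@pytest.fixture(scope="session")
def strength_40(optics_config) -> complex:
    return gnp_scatterer_strength(40.0, optics_config)


@pytest.fixture(scope="session")
def small_stack(optics_config):
    """Fine-grid stack over a 1 um band below focus (fast to build)."""
    return build_model_stack(optics_config, 1_500.0, 2_500.0, 2.0,
                             n_bins=40, r_max_px=40.0)


@pytest.fixture(scope="session")
def tracking_stack(optics_config):
    """Full-range 1 nm stack used by the end-to-end tracking tests."""
    return build_model_stack(optics_config, 0.0, 4_500.0, 1.0,
                             n_bins=50, r_max_px=50.0)
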