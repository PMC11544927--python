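"""Frame normalization, background correction, RVT localization and
radial-profile extraction."""

import numpy as np
import pytest

from ispt3d.optics import compute_ipsf_image, gnp_scatterer_strength
from ispt3d.preprocess import (LateralTrack, extract_profiles,
                               intensity_peak_localize,
                               normalize_frame_power, rvt_localize, rvt_map,
                               temporal_median_background)
from ispt3d.simulate import ContrastVideo, Trajectory3D, render_video


# ------------------------------------------------------------ normalization

def test_normalization_is_scale_invariant():
    rng = np.random.default_rng(0)
    video = rng.uniform(1.0, 2.0, size=(6, 16, 16))
    scaled = video * np.array([1.0, 3.7, 0.2, 11.0, 5.5, 0.9])[:, None, None]
    a = normalize_frame_power(video).frames
    b = normalize_frame_power(scaled).frames
    # frame-wise scale differences vanish; only the global mean-sum differs
    assert np.allclose(a / a[0], b / b[0], rtol=1e-12)


def test_normalization_flattens_intensity_drift():
    rng = np.random.default_rng(1)
    scene = rng.uniform(900.0, 1100.0, size=(16, 16))
    drift = 1.0 + 0.01 * np.arange(50)
    video = scene[None] * drift[:, None, None]
    out = normalize_frame_power(video).frames
    assert out.std(axis=0).max() < 1e-4 * out.mean()


def test_normalization_rejects_zero_sum_frame():
    video = np.ones((3, 4, 4))
    video[1] = 0.0
    with pytest.raises(ValueError, match="frame 1"):
        normalize_frame_power(video)


# ------------------------------------------------------------ median bkg

def test_static_video_gives_zero_contrast():
    video = np.tile(np.random.default_rng(2).uniform(500, 600, (8, 8)), (9, 1, 1))
    out = temporal_median_background(video, 3).frames
    assert np.abs(out).max() < 1e-12


def test_single_frame_impulse_survives_median():
    video = np.full((9, 8, 8), 100.0)
    video[4, 3, 3] += 55.0
    out = temporal_median_background(video, 5).frames
    assert out[4, 3, 3] == pytest.approx(0.55)
    out[4, 3, 3] = 0.0
    assert np.abs(out).max() < 1e-12


def test_moving_particle_contrast_preserved(optics_config, strength_40):
    """A particle displacing >> PSF width inside the window survives the
    median correction within 5% of the noiseless render."""
    n = 15
    positions = np.column_stack([
        np.linspace(-1_600, 1_600, n), np.zeros(n), np.full(n, 3_200.0)])
    traj = Trajectory3D(times=1e-5 * np.arange(n), positions=positions,
                        frame_interval=1e-5)
    clean = render_video(traj, optics_config, sigma_n=0.0, image_size=61,
                         scatterer_strength=strength_40)
    raw = 1_000.0 * (1.0 + clean.frames)
    out = temporal_median_background(raw, 15).frames
    mid = n // 2
    ref = clean.frames[mid]
    # preserved within 5% of the render's contrast amplitude
    assert np.abs(out[mid] - ref).max() < 0.05 * np.abs(ref).max()


def test_median_rejects_nonpositive_reference():
    video = np.full((5, 4, 4), -1.0)
    video[2, 0, 0] = 5.0
    with pytest.raises(ValueError, match="reference"):
        temporal_median_background(video, 3)


# ------------------------------------------------------------ RVT

def _ring_image(size, cx, cy, radius=8.0):
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(xx - cx, yy - cy)
    return np.exp(-0.5 * ((dist - radius) / 1.0) ** 2)


def test_rvt_finds_centered_ring():
    img = _ring_image(41, 20.0, 20.0)
    x, y, conf = rvt_localize(img, 3, 14)
    assert x == pytest.approx(20.0, abs=0.01)
    assert y == pytest.approx(20.0, abs=0.01)
    assert conf > 0.3


def test_rvt_translation_equivariance():
    base = rvt_localize(_ring_image(41, 20.0, 20.0), 3, 14)
    shifted = rvt_localize(_ring_image(41, 23.0, 18.0), 3, 14)
    assert shifted[0] - base[0] == pytest.approx(3.0, abs=0.05)
    assert shifted[1] - base[1] == pytest.approx(-2.0, abs=0.05)


def test_rvt_map_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    img = _ring_image(32, 15.0, 17.0) + 0.05 * rng.normal(size=(32, 32))
    r_min, r_max = 2, 6
    t = rvt_map(img, r_min, r_max, 1)
    yy, xx = np.mgrid[0:32, 0:32]
    oracle = np.zeros((32, 32))
    for cy in range(32):
        for cx in range(32):
            dist = np.hypot(xx - cx, yy - cy)
            mus, var_s = [], []
            for r in range(r_min, r_max + 1):
                ring = (dist >= r - 0.5) & (dist < r + 0.5)
                # zero-padding convention: fixed per-radius pixel count
                full = np.hypot(np.mgrid[-r_max - 1:r_max + 2,
                                         -r_max - 1:r_max + 2][0],
                                np.mgrid[-r_max - 1:r_max + 2,
                                         -r_max - 1:r_max + 2][1])
                n_r = int(((full >= r - 0.5) & (full < r + 0.5)).sum())
                vals = img[ring]
                mu = vals.sum() / n_r
                q = (vals ** 2).sum() / n_r
                mus.append(mu)
                var_s.append(q - mu * mu)
            mus = np.array(mus)
            oracle[cy, cx] = mus.var() - np.mean(var_s)
    assert np.allclose(t, oracle, atol=1e-10)


def test_rvt_on_rendered_ipsf_is_subpixel(optics_config, strength_40):
    """Noiseless iPSF at random sub-pixel offsets: RMS error < 0.1 px."""
    rng = np.random.default_rng(8)
    px = optics_config.pixel_size_sample
    errors = []
    for _ in range(20):
        off = rng.uniform(-1.5, 1.5, size=2) * px
        img = compute_ipsf_image(optics_config, 2_000.0, tuple(off),
                                 strength_40, 81).pixels
        x, y, _ = rvt_localize(img, 2, 24, 2, confidence_floor=0.0)
        errors.append([x - (40 + off[0] / px), y - (40 + off[1] / px)])
    rms = np.sqrt(np.mean(np.square(errors)))
    assert rms < 0.1


def test_rvt_flags_featureless_frame():
    rng = np.random.default_rng(0)
    assert rvt_localize(rng.normal(0, 1e-3, (64, 64)), 2, 24, 2) is None


# ------------------------------------------------------------ profiles

def test_profiles_of_static_video_are_identical(optics_config, strength_40):
    pos = np.tile([0.0, 0.0, 2_000.0], (5, 1))
    traj = Trajectory3D(times=1e-5 * np.arange(5), positions=pos,
                        frame_interval=1e-5)
    video = render_video(traj, optics_config, sigma_n=0.0, image_size=81,
                         scatterer_strength=strength_40)
    track = LateralTrack(frames=np.arange(5), x_px=np.full(5, 40.0),
                         y_px=np.full(5, 40.0), confidence=np.ones(5))
    series = extract_profiles(video, track, 40, 40.0, config=optics_config)
    assert np.allclose(series.values, series.values[0], atol=1e-12)


def test_profiles_track_model_rows_on_a_ramp(optics_config, small_stack):
    z_idx = [50, 150, 250, 350]
    zs = small_stack.z_grid[z_idx]
    pos = np.column_stack([np.zeros(4), np.zeros(4), zs])
    traj = Trajectory3D(times=1e-5 * np.arange(4), positions=pos,
                        frame_interval=1e-5)
    video = render_video(traj, optics_config, sigma_n=0.0, image_size=81,
                         scatterer_strength=small_stack.scatterer_strength)
    track = LateralTrack(frames=np.arange(4), x_px=np.full(4, 40.0),
                         y_px=np.full(4, 40.0), confidence=np.ones(4))
    series = extract_profiles(video, track, 40, 40.0, config=optics_config)
    for row, idx in zip(series.values, z_idx):
        model = small_stack.profiles[idx]
        rho = np.corrcoef(row, model)[0, 1]
        assert rho > 0.999


def test_center_gaps_are_interpolated_and_long_gaps_dropped(optics_config,
                                                            strength_40):
    pos = np.tile([0.0, 0.0, 2_000.0], (14, 1))
    traj = Trajectory3D(times=1e-5 * np.arange(14), positions=pos,
                        frame_interval=1e-5)
    video = render_video(traj, optics_config, sigma_n=0.0, image_size=81,
                         scatterer_strength=strength_40)
    x = np.full(14, 40.0)
    x[3:5] = np.nan          # short gap: interpolated
    x[7:14] = np.nan         # trailing long gap: dropped
    track = LateralTrack(frames=np.arange(14), x_px=x,
                         y_px=np.full(14, 40.0), confidence=np.ones(14))
    series = extract_profiles(video, track, 20, 20.0, config=optics_config)
    assert set(series.frames) == {0, 1, 2, 3, 4, 5, 6}
    assert set(series.dropped_frames) == set(range(7, 14))


def test_second_defocused_particle_barely_perturbs_profile(optics_config,
                                                           strength_40):
    """Azimuthal averaging dilutes an off-center intruder's rings."""
    main = compute_ipsf_image(optics_config, 2_000.0, (0, 0), strength_40,
                              101).pixels
    intruder = compute_ipsf_image(optics_config, 4_000.0, (3_500.0, 3_500.0),
                                  strength_40, 101).pixels
    video = ContrastVideo(frames=np.stack([main, main + intruder]),
                          frame_interval=1e-5,
                          pixel_size=optics_config.pixel_size_sample)
    track = LateralTrack(frames=np.arange(2), x_px=np.full(2, 50.0),
                         y_px=np.full(2, 50.0), confidence=np.ones(2))
    series = extract_profiles(video, track, 30, 30.0, config=optics_config)
    clean, dirty = series.values
    scale = np.abs(clean).max()
    assert np.abs(dirty - clean).max() < 0.05 * scale
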