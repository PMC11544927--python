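"""Correlation map, region selection, branch graph, debranching and
polynomial refinement."""


import numpy as np
import pytest

from ispt3d.axial import (CorrelationMap, build_branch_graph, correlation_map,
                          count_paths, label_regions, refine_axial,
                          shortest_path_debranch, track_axial)
from ispt3d.preprocess import LateralTrack, RadialProfileSeries, extract_profiles
from ispt3d.simulate import Trajectory3D, render_video


def _series(values, radii=None):
    values = np.asarray(values, dtype=float)
    if radii is None:
        radii = np.arange(values.shape[1], dtype=float) + 0.5
    return RadialProfileSeries(frames=np.arange(values.shape[0]),
                               radii=radii, values=values)


def _cmap(rho, z_step=1.0):
    rho = np.asarray(rho, dtype=float)
    return CorrelationMap(rho=rho, z_grid=z_step * np.arange(rho.shape[1]),
                          frames=np.arange(rho.shape[0]))


# ---------------------------------------------------------- correlation map

def test_correlation_extremes(small_stack):
    row = small_stack.profiles[37]
    series = _series(np.vstack([row, -row]), radii=small_stack.radii)
    cmap = correlation_map(series, small_stack)
    assert cmap.rho[0, 37] == pytest.approx(1.0, abs=1e-6)
    assert cmap.rho[1, 37] == pytest.approx(-1.0, abs=1e-6)


def test_correlation_matches_bruteforce_pearson(small_stack):
    rng = np.random.default_rng(0)
    series = _series(rng.normal(size=(5, small_stack.radii.size)),
                     radii=small_stack.radii)
    sub = small_stack.profiles[:7]
    cmap = correlation_map(series, small_stack)
    for i in range(5):
        for k in range(7):
            x, y = series.values[i], sub[k]
            oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert cmap.rho[i, k] == pytest.approx(oracle, abs=1e-6)


def test_correlation_flags_flat_profile(small_stack):
    vals = np.vstack([small_stack.profiles[0],
                      np.zeros(small_stack.radii.size)])
    cmap = correlation_map(_series(vals, radii=small_stack.radii), small_stack)
    assert list(cmap.undefined_frames) == [1]
    assert np.all(cmap.rho[1] == 0.0)
    assert np.all(np.isfinite(cmap.rho))


# ---------------------------------------------------------- region labeling

def test_single_stripe_scores_as_sum_of_maxima():
    rho = -np.ones((4, 6))
    rho[:, 2] = [0.5, 0.6, 0.7, 0.8]
    labeling = label_regions(_cmap(rho))
    assert labeling.n_regions == 1
    assert labeling.scores[labeling.selected_label] == pytest.approx(2.6)


def test_two_blob_toy_map_matches_hand_enumeration():
    rho = np.full((4, 6), -1.0)
    # blob A: frames 0-1, z 0-1 ; blob B: frames 1-3, z 4-5 (disjoint, 8-conn)
    rho[0, 0], rho[0, 1] = 0.9, 0.2
    rho[1, 0] = 0.4
    rho[1, 4], rho[2, 4], rho[2, 5], rho[3, 5] = 0.3, 0.8, 0.1, 0.6
    labeling = label_regions(_cmap(rho))
    assert labeling.n_regions == 2
    label_a = labeling.labels[0, 0]
    label_b = labeling.labels[1, 4]
    # hand-computed per-frame maxima: A -> 0.9 + 0.4; B -> 0.3 + 0.8 + 0.6
    assert labeling.scores[label_a] == pytest.approx(1.3)
    assert labeling.scores[label_b] == pytest.approx(1.7)
    assert labeling.selected_label == label_b


def test_empty_map_is_an_error():
    with pytest.raises(ValueError):
        label_regions(_cmap(-np.ones((3, 3))))


# ---------------------------------------------------------- branch graph

def test_single_branch_graph_distance():
    rho = np.full((5, 7), -1.0)
    rho[:, 3] = [0.9, 0.8, 0.7, 0.95, 0.85]
    cmap = _cmap(rho)
    labeling = label_regions(cmap)
    (bg,) = build_branch_graph(cmap, labeling.selected_mask())
    assert count_paths(bg) == 1
    path = shortest_path_debranch(bg)
    assert path.total_distance == pytest.approx(5 - rho[:, 3].sum())


def _toggle_map(n_episodes, n_z=12, gap_frames=1):
    """Single branch toggling to two branches n_episodes times."""
    rows = []
    single = np.full(n_z, -1.0)
    single[4:9] = 0.8
    double = np.full(n_z, -1.0)
    double[3:6] = 0.7      # low-z branch
    double[7:10] = 0.6     # high-z branch (z index 6 stays below threshold)
    rows.append(single)
    for _ in range(n_episodes):
        rows.append(double)
        for _ in range(gap_frames):
            rows.append(single)
    return _cmap(np.vstack(rows))


def test_toggle_once_gives_four_nodes_four_edges_two_paths():
    cmap = _toggle_map(1)
    labeling = label_regions(cmap)
    (bg,) = build_branch_graph(cmap, labeling.selected_mask())
    assert bg.graph.number_of_nodes() == 4     # source, 2 boundaries, sink
    assert bg.graph.number_of_edges() == 4
    assert count_paths(bg) == 2


def test_23_toggles_give_2_to_the_23_paths():
    cmap = _toggle_map(23)
    labeling = label_regions(cmap)
    (bg,) = build_branch_graph(cmap, labeling.selected_mask())
    assert count_paths(bg) == 2 ** 23 == 8_388_608


def test_perfect_correlation_gives_zero_distances():
    rho = np.full((4, 8), -1.0)
    rho[:, 2:5] = 1.0
    cmap = _cmap(rho)
    (bg,) = build_branch_graph(cmap, label_regions(cmap).selected_mask())
    weights = [d["weight"] for *_, d in bg.graph.edges(data=True)]
    assert all(w == pytest.approx(0.0) for w in weights)


def test_zero_branch_frame_splits_segments():
    rho = np.full((5, 6), -1.0)
    rho[[0, 1], 2] = 0.9
    rho[[3, 4], 2] = 0.8
    rho[2, 2] = 0.9        # bridge frame ...
    cmap = _cmap(rho)
    mask = label_regions(cmap).selected_mask()
    mask[2] = False        # ... removed: zero branches inside the span
    graphs = build_branch_graph(cmap, mask)
    assert len(graphs) == 2
    assert graphs[0].frame_end == 1 and graphs[1].frame_start == 3


# ---------------------------------------------------------- debranching

def _enumerate_paths(bg):
    """Exhaustive DFS over parallel edges: (total weight, edge datas)."""
    out = []

    def walk(node, weight, edges):
        if node == bg.sink:
            out.append((weight, list(edges)))
            return
        for _, v, k, d in bg.graph.out_edges(node, keys=True, data=True):
            edges.append(d)
            walk(v, weight + d["weight"], edges)
            edges.pop()

    walk(bg.source, 0.0, [])
    return out


@pytest.mark.parametrize("seed", range(8))
def test_debranching_equals_exhaustive_enumeration(seed):
    """On random striped maps with <= 2^10 paths the DAG shortest path is
    exactly the global maximizer of the summed correlation."""
    rng = np.random.default_rng(seed)
    rho = rng.uniform(-1.0, 1.0, size=(10, 16))
    rho[:, ::3] = np.abs(rho[:, ::3])      # guarantee some positive stripes
    cmap = _cmap(rho)
    labeling = label_regions(cmap)
    for bg in build_branch_graph(cmap, labeling.selected_mask()):
        n_paths = count_paths(bg)
        paths = _enumerate_paths(bg)
        assert len(paths) == n_paths
        if n_paths > 1024:
            continue
        best_weight = min(w for w, _ in paths)
        path = shortest_path_debranch(bg)
        assert path.total_distance == pytest.approx(best_weight, abs=1e-9)


def test_exact_tie_prefers_lower_branch_and_flags():
    rho = np.full((3, 12), -1.0)
    rho[:, 4:9] = 0.8                       # single entry branch
    rho[1, 4:6] = [0.9, 0.9]
    rho[1, 6] = -1.0                        # split frame: two branches
    rho[1, 7:9] = [0.9, 0.9]                # identical correlation values
    cmap = _cmap(rho)
    (bg,) = build_branch_graph(cmap, label_regions(cmap).selected_mask())
    path = shortest_path_debranch(bg)
    assert path.ambiguous
    row = path.frames.tolist().index(1)
    assert path.intervals[row][0] == 4      # lower-z branch chosen


# ---------------------------------------------------------- refinement

def test_refine_recovers_exact_parabola_peak():
    z = np.arange(30.0)
    z0 = 14.37
    rho = 1.0 - 0.002 * (z - z0) ** 2
    z_hat, flags = refine_axial(rho, z, (10, 20), window=3, z_step=1.0)
    assert z_hat == pytest.approx(z0, abs=1e-6)
    assert flags["degree"] >= 2


def test_refine_flat_column_returns_center_flagged():
    rho = np.full(11, 0.5)
    z = np.arange(11.0)
    z_hat, flags = refine_axial(rho, z, (2, 8), window=3)
    assert flags["degenerate"]
    assert 2.0 <= z_hat <= 8.0


def test_refine_single_point_branch_unrefined():
    rho = np.full(5, -1.0)
    rho[2] = 0.7
    z_hat, flags = refine_axial(rho, np.arange(5.0), (2, 2))
    assert flags["unrefined"] and z_hat == 2.0


def test_refine_against_dense_grid_oracle(optics_config, small_stack):
    """Correlation of a profile at an off-grid height peaks within 0.5 nm of
    a dense-grid argmax oracle (profiles generated through the same
    render-and-bin path as the model rows)."""
    from ispt3d.optics import radial_profile_resampled
    from ispt3d.simulate import render_frame

    def binned_profile(z):
        img = render_frame(optics_config, (0.0, 0.0, z), 81,
                           small_stack.scatterer_strength)
        return radial_profile_resampled(
            img, (40, 40), 40, 40.0,
            pixel_size=optics_config.pixel_size_sample).values

    true_z = 2_000.7
    prof = binned_profile(true_z)
    series = _series(prof[None, :], radii=small_stack.radii)
    track = track_axial(series, small_stack)
    # oracle: dense (0.01 nm) argmax of the correlation against rendered
    # model profiles near the truth
    dense_z = np.arange(true_z - 3.0, true_z + 3.0, 0.01)
    dense_rho = [np.corrcoef(prof, binned_profile(z))[0, 1] for z in dense_z]
    oracle = dense_z[int(np.argmax(dense_rho))]
    assert track.z_nm[0] == pytest.approx(oracle, abs=0.5)


# ---------------------------------------------------------- stripe pattern

def test_correlation_stripes_near_carrier_period(optics_config):
    """rho along z is striped at approximately lambda/(2 n_m).

    The stripe spacing runs a few percent above the on-axis carrier
    because the profile's rings map to oblique pupil rays, whose axial
    phase advances at k n (1 + cos theta) < 2 k n; the on-axis carrier
    itself (central contrast) is tested at 2% elsewhere.  Here the
    zero-crossing period of a correlation column over a 2 um window at
    moderate defocus must stay within 5% of lambda/(2 n_m).
    """
    from ispt3d.optics import build_model_stack
    stack = build_model_stack(optics_config, 4_200.0, 6_200.0, 1.0,
                              n_bins=50, r_max_px=50.0)
    mid = stack.profiles.shape[0] // 2
    ref = stack.profiles[mid]
    series = _series(ref[None, :], radii=stack.radii)
    cmap = correlation_map(series, stack)
    col = cmap.rho[0].astype(float) - float(cmap.rho[0].mean())
    crossings = np.flatnonzero(np.signbit(col[:-1]) != np.signbit(col[1:]))
    period = 2.0 * (crossings[-1] - crossings[0]) / (crossings.size - 1)
    assert period == pytest.approx(optics_config.carrier_period, rel=0.05)


# ---------------------------------------------------------- end to end

def test_noiseless_ramp_tracks_within_grid_step(optics_config, tracking_stack):
    zs = np.arange(200.0, 4_300.0, 50.0)
    n = zs.size
    pos = np.column_stack([np.zeros(n), np.zeros(n), zs])
    traj = Trajectory3D(times=1e-5 * np.arange(n), positions=pos,
                        frame_interval=1e-5)
    video = render_video(traj, optics_config, sigma_n=0.0, image_size=101,
                         scatterer_strength=tracking_stack.scatterer_strength)
    track = LateralTrack(frames=np.arange(n), x_px=np.full(n, 50.0),
                         y_px=np.full(n, 50.0), confidence=np.ones(n))
    series = extract_profiles(video, track, 50, 50.0, config=optics_config)
    result = track_axial(series, tracking_stack)
    err = result.z_nm - zs
    assert np.isfinite(err).all()
    assert np.abs(err).max() < tracking_stack.z_step
    # the debranched track is single-valued and moves less than half a stripe
    dz = np.abs(np.diff(result.z_nm))
    assert dz.max() < optics_config.carrier_period / 2.0


def test_graph_method_avoids_cross_focus_jumps(optics_config, tracking_stack):
    """Naive per-frame argmax jumps across the focal plane; the graph path
    does not."""
    rng = np.random.default_rng(2)
    z_f = optics_config.focal_plane_z
    zs = z_f + 280.0 * np.sin(np.linspace(0, 4 * np.pi, 160))
    pos = np.column_stack([np.zeros(zs.size), np.zeros(zs.size), zs])
    traj = Trajectory3D(times=1e-5 * np.arange(zs.size), positions=pos,
                        frame_interval=1e-5)
    # a weak (20 nm-like) scatterer makes the per-frame argmax fragile
    video = render_video(traj, optics_config, sigma_n=6.56e-3,
                         noise_seed=rng, image_size=101,
                         scatterer_strength=tracking_stack.scatterer_strength / 8)
    track = LateralTrack(frames=np.arange(zs.size),
                         x_px=np.full(zs.size, 50.0),
                         y_px=np.full(zs.size, 50.0),
                         confidence=np.ones(zs.size))
    series = extract_profiles(video, track, 50, 50.0, config=optics_config)
    cmap = correlation_map(series, tracking_stack)
    naive = cmap.z_grid[np.argmax(cmap.rho, axis=1)]
    limit = optics_config.carrier_period / 2.0
    naive_jumps = int(np.sum(np.abs(np.diff(naive)) > limit))
    result = track_axial(series, tracking_stack)
    graph_jumps = int(np.nansum(np.abs(np.diff(result.z_nm)) > limit))
    assert naive_jumps > 0
    assert graph_jumps == 0
    assert np.nanstd(result.z_nm - zs) < 25.0
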