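"""Axial localization from correlation maps via region selection, a branch
graph, shortest-path debranching and sub-grid polynomial refinement.

The interferometric carrier phase makes the per-frame correlation between an
experimental radial profile and the model stack oscillate along ``z`` with
period ``lambda/(2 n)``, so the map of Pearson values rho(i, z) is striped
and locally ambiguous: stripes above and below the focal plane mirror each
other, and near focus their maxima nearly tie.  Frame-by-frame argmax
assignment therefore jumps between stripes.  Instead, the tracker

1. thresholds the map at zero and selects the connected region with the
   highest summed per-frame maximum correlation,
2. represents that region as a directed acyclic graph whose edges are
   constant-branch-count sections weighted by ``sum_i (1 - max_z rho)``,
3. picks the minimum-distance source-to-sink path (Dijkstra / DAG dynamic
   programming), which maximizes the total correlation along the video, and
4. refines each frame's height beyond the model grid with a low-order
   polynomial fit around the winning branch's peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .optics import RadialModelStack
from .preprocess import RadialProfileSeries

__all__ = [
    "CorrelationMap",
    "RegionLabeling",
    "BranchGraph",
    "DebranchedPath",
    "AxialTrack",
    "correlation_map",
    "label_regions",
    "build_branch_graph",
    "count_paths",
    "shortest_path_debranch",
    "refine_axial",
    "track_axial",
]


@dataclass
class CorrelationMap:
    """Frames x z-grid matrix of Pearson correlations, entries in [-1, 1]."""

    rho: np.ndarray
    z_grid: np.ndarray
    frames: np.ndarray                      # frame indices of the rows
    undefined_frames: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho)
        if self.rho.ndim != 2:
            raise ValueError("rho must be 2-D (frames x z)")
        if self.rho.shape[1] != len(self.z_grid):
            raise ValueError("rho column count must match z_grid")

    @property
    def z_step(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0]) if len(self.z_grid) > 1 else 1.0


def correlation_map(profiles: RadialProfileSeries,
                    model: RadialModelStack) -> CorrelationMap:
    """Pearson correlation over r between every frame profile and model row.

    The model is resampled onto the experimental radii by linear
    interpolation when the grids differ; experimental radii outside the
    model's range are a hard error.  Frames whose profile has zero variance
    are flagged and yield an all-zero row rather than NaNs.
    """
    radii = profiles.radii
    m_radii = model.radii
    if radii[0] < m_radii[0] - 1e-6 or radii[-1] > m_radii[-1] + 1e-6:
        raise ValueError("experimental radii extend beyond the model's; "
                         "rebuild the model stack with a larger r_max")
    if len(radii) == len(m_radii) and np.allclose(radii, m_radii):
        rows = model.profiles
    else:
        rows = np.vstack([np.interp(radii, m_radii, row)
                          for row in model.profiles])
    e = np.asarray(profiles.values, dtype=np.float64)
    e_std = e.std(axis=1)
    undefined = np.flatnonzero(e_std == 0)
    e_std = np.where(e_std == 0, 1.0, e_std)
    ez = (e - e.mean(axis=1, keepdims=True)) / e_std[:, None]
    m_std = rows.std(axis=1)
    if np.any(m_std == 0):
        raise ValueError("model stack contains a zero-variance row")
    mz = (rows - rows.mean(axis=1, keepdims=True)) / m_std[:, None]
    rho = (ez @ mz.T) / radii.size
    rho[undefined] = 0.0
    rho = np.clip(rho, -1.0, 1.0).astype(np.float32)
    return CorrelationMap(rho=rho, z_grid=model.z_grid,
                          frames=np.asarray(profiles.frames),
                          undefined_frames=undefined)


@dataclass
class RegionLabeling:
    """8-connected components of the suprathreshold correlation map."""

    labels: np.ndarray            # int labels, 0 = below threshold
    scores: np.ndarray            # scores[j] for label j (scores[0] = -inf)
    pixel_counts: np.ndarray
    selected_label: int

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def selected_mask(self) -> np.ndarray:
        return self.labels == self.selected_label


def label_regions(cmap: CorrelationMap, threshold: float = 0.0) -> RegionLabeling:
    """Label connected positive regions and select the best-scoring one.

    Each region's score is the sum over its frames of the region's maximum
    correlation in that frame; the region with the highest score wins (ties
    broken by larger pixel count, then smaller label).
    """
    rho = np.asarray(cmap.rho)
    if not np.all(np.isfinite(rho)):
        raise ValueError("correlation map contains non-finite values")
    mask = rho > threshold
    if not mask.any():
        raise ValueError("no suprathreshold region in the correlation map")
    labels, n_regions = ndimage.label(mask, structure=np.ones((3, 3), int))
    n_frames = rho.shape[0]
    # per-(label, frame) maximum via a dense scatter-max
    flat_label = labels[mask]
    flat_frame = np.nonzero(mask)[0]
    key = flat_label.astype(np.int64) * n_frames + flat_frame
    per_lf = np.full((n_regions + 1) * n_frames, -np.inf)
    np.maximum.at(per_lf, key, rho[mask].astype(np.float64))
    per_lf = per_lf.reshape(n_regions + 1, n_frames)
    present = np.isfinite(per_lf)
    scores = np.where(present, per_lf, 0.0).sum(axis=1)
    scores[0] = -np.inf
    pixel_counts = np.bincount(flat_label, minlength=n_regions + 1)
    order = np.lexsort((np.arange(n_regions + 1),
                        -pixel_counts.astype(np.int64),
                        -scores))
    selected = int(order[0])
    return RegionLabeling(labels=labels, scores=scores,
                          pixel_counts=pixel_counts, selected_label=selected)


# --------------------------------------------------------------------------
# branch graph

@dataclass
class _Section:
    """Maximal frame span over which the branch count and pairing persist."""

    frame_start: int                  # row index into the map
    frame_end: int                    # inclusive
    runs: list                        # runs[branch][frame_offset] = (lo, hi)
    peak_idx: np.ndarray              # (n_branches, n_frames) argmax z index
    peak_rho: np.ndarray              # (n_branches, n_frames)

    @property
    def n_branches(self) -> int:
        return len(self.runs)

    def distance(self, branch: int) -> float:
        return float(np.sum(1.0 - self.peak_rho[branch]))


@dataclass
class BranchGraph:
    """DAG of constant-branch-count sections of the selected region.

    Nodes are branching points (plus ``source``/``sink``); parallel edges
    carry the alternative branches of a section together with nonnegative
    distances ``sum_i (1 - max_z rho(i, z))``.
    """

    graph: nx.MultiDiGraph
    source: str
    sink: str
    sections: list
    frame_start: int
    frame_end: int                    # inclusive row index


def _frame_runs(row_mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs (inclusive index intervals) of a boolean row."""
    if not row_mask.any():
        return []
    d = np.diff(row_mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if row_mask[0]:
        starts = np.concatenate(([0], starts))
    if row_mask[-1]:
        ends = np.concatenate((ends, [row_mask.size - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """8-connectivity between z-intervals of consecutive frames."""
    return a[0] <= b[1] + 1 and b[0] <= a[1] + 1


def build_branch_graph(cmap: CorrelationMap,
                       mask: np.ndarray) -> list[BranchGraph]:
    """Graphs of the selected region, one per temporally contiguous segment.

    Frames inside the region's span with no suprathreshold pixel split the
    trajectory into segments, as do rare boundaries where no branch of one
    frame touches any branch of the next (stripe linking broken).
    """
    rho = np.asarray(cmap.rho, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("selected region is empty")
    frames_with = np.flatnonzero(mask.any(axis=1))
    runs_by_frame = {int(i): _frame_runs(mask[i]) for i in frames_with}
    # split into contiguous frame segments
    segments: list[list[int]] = []
    current = [int(frames_with[0])]
    for i in frames_with[1:]:
        if int(i) == current[-1] + 1:
            current.append(int(i))
        else:
            segments.append(current)
            current = [int(i)]
    segments.append(current)
    # further split where consecutive frames share no adjacent runs
    final_segments: list[list[int]] = []
    for seg in segments:
        piece = [seg[0]]
        for i in seg[1:]:
            left, right = runs_by_frame[i - 1], runs_by_frame[i]
            if any(_adjacent(a, b) for a in left for b in right):
                piece.append(i)
            else:
                final_segments.append(piece)
                piece = [i]
        final_segments.append(piece)
    return [_segment_graph(rho, runs_by_frame, seg) for seg in final_segments]


def _segment_graph(rho: np.ndarray, runs_by_frame: dict,
                   seg_frames: list[int]) -> BranchGraph:
    # carve the segment into sections of constant, continuously paired runs
    sections: list[_Section] = []
    sec_frames = [seg_frames[0]]
    sec_runs = [[run] for run in runs_by_frame[seg_frames[0]]]
    for i in seg_frames[1:]:
        prev = [br[-1] for br in sec_runs]
        cur = runs_by_frame[i]
        contiguous = (len(prev) == len(cur)
                      and all(_adjacent(a, b) for a, b in zip(prev, cur)))
        if contiguous:
            sec_frames.append(i)
            for br, run in zip(sec_runs, cur):
                br.append(run)
        else:
            sections.append(_close_section(rho, sec_frames, sec_runs))
            sec_frames = [i]
            sec_runs = [[run] for run in cur]
    sections.append(_close_section(rho, sec_frames, sec_runs))

    g = nx.MultiDiGraph()
    source, sink = "source", "sink"
    g.add_node(source, time=-1)
    g.add_node(sink, time=len(sections))
    left_nodes: list = []          # per section: node id for each branch start
    # assign nodes at boundaries by grouping adjacent (left, right) branches
    node_count = 0
    starts: list[list] = []
    ends: list[list] = []
    for s_idx, sec in enumerate(sections):
        starts.append([None] * sec.n_branches)
        ends.append([None] * sec.n_branches)
    for s_idx in range(len(sections) - 1):
        left = sections[s_idx]
        right = sections[s_idx + 1]
        l_runs = [br[-1] for br in left.runs]
        r_runs = [br[0] for br in right.runs]
        # connected components of the bipartite adjacency between sections
        parent = list(range(len(l_runs) + len(r_runs)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for li, lr in enumerate(l_runs):
            for ri, rr in enumerate(r_runs):
                if _adjacent(lr, rr):
                    ra, rb = find(li), find(len(l_runs) + ri)
                    if ra != rb:
                        parent[rb] = ra
        comp_node: dict[int, str] = {}
        for li in range(len(l_runs)):
            root = find(li)
            if root not in comp_node:
                comp_node[root] = f"n{node_count}"
                g.add_node(comp_node[root], time=s_idx)
                node_count += 1
            ends[s_idx][li] = comp_node[root]
        for ri in range(len(r_runs)):
            root = find(len(l_runs) + ri)
            if root not in comp_node:
                comp_node[root] = f"n{node_count}"
                g.add_node(comp_node[root], time=s_idx)
                node_count += 1
            starts[s_idx + 1][ri] = comp_node[root]
    for b in range(sections[0].n_branches):
        starts[0][b] = source
    for b in range(sections[-1].n_branches):
        ends[-1][b] = sink
    for s_idx, sec in enumerate(sections):
        for b in range(sec.n_branches):
            mean_z = float(np.mean([0.5 * (lo + hi) for lo, hi in sec.runs[b]]))
            g.add_edge(starts[s_idx][b], ends[s_idx][b],
                       weight=sec.distance(b), section=s_idx, branch=b,
                       mean_z=mean_z)
    return BranchGraph(graph=g, source=source, sink=sink, sections=sections,
                       frame_start=seg_frames[0], frame_end=seg_frames[-1])


def _close_section(rho: np.ndarray, frames: list[int],
                   runs: list[list]) -> _Section:
    n_b, n_f = len(runs), len(frames)
    peak_idx = np.zeros((n_b, n_f), dtype=np.intp)
    peak_rho = np.zeros((n_b, n_f))
    for b in range(n_b):
        for k, i in enumerate(frames):
            lo, hi = runs[b][k]
            seg = rho[i, lo:hi + 1]
            j = int(np.argmax(seg))
            peak_idx[b, k] = lo + j
            peak_rho[b, k] = seg[j]
    return _Section(frame_start=frames[0], frame_end=frames[-1],
                    runs=runs, peak_idx=peak_idx, peak_rho=peak_rho)


def count_paths(bg: BranchGraph) -> int:
    """Number of distinct source-to-sink paths (edges counted individually)."""
    g = bg.graph
    counts = {bg.source: 1}
    for node in nx.topological_sort(g):
        c = counts.get(node, 0)
        if c == 0 and node != bg.source:
            continue
        for _, v, _ in g.out_edges(node, keys=True):
            counts[v] = counts.get(v, 0) + c
    return counts.get(bg.sink, 0)


@dataclass
class DebranchedPath:
    """Single branch per frame after shortest-path selection."""

    frames: np.ndarray          # row indices covered
    intervals: np.ndarray       # (n, 2) inclusive z-index intervals
    peak_idx: np.ndarray        # per-frame argmax z index within the branch
    peak_rho: np.ndarray
    total_distance: float
    ambiguous: bool = False

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for f, (lo, hi) in zip(self.frames, self.intervals):
            mask[f, lo:hi + 1] = True
        return mask


def shortest_path_debranch(bg: BranchGraph) -> DebranchedPath:
    """Minimum-distance source-to-sink path, one branch per frame.

    Because edge distances are ``sum_i (1 - max_z rho)`` and every path
    covers every frame of the segment exactly once, the minimum-distance
    path is exactly the maximizer of the summed per-frame correlation.
    Exact ties are resolved toward the lower-z branch and flagged.
    """
    g = bg.graph
    dist: dict = {bg.source: 0.0}
    back: dict = {}
    ambiguous = False
    for node in nx.topological_sort(g):
        if node not in dist:
            continue
        for _, v, k, data in g.out_edges(node, keys=True, data=True):
            cand = dist[node] + data["weight"]
            if v not in dist or cand < dist[v] - 1e-12:
                dist[v] = cand
                back[v] = (node, k, data)
            elif abs(cand - dist[v]) <= 1e-12:
                # exact tie between alternative branches: deterministic
                # preference for the lower-z branch, flagged ambiguous
                ambiguous = True
                incumbent = back[v][2]
                if data["mean_z"] < incumbent["mean_z"] - 1e-12:
                    back[v] = (node, k, data)
    if bg.sink not in dist:
        raise ValueError("sink unreachable: segment graph is disconnected")
    chosen: list = []
    node = bg.sink
    while node != bg.source:
        node, _, data = back[node]
        chosen.append(data)
    chosen.reverse()
    frames, intervals, pk_idx, pk_rho = [], [], [], []
    for data in chosen:
        sec = bg.sections[data["section"]]
        b = data["branch"]
        for k, i in enumerate(range(sec.frame_start, sec.frame_end + 1)):
            frames.append(i)
            intervals.append(sec.runs[b][k])
            pk_idx.append(sec.peak_idx[b, k])
            pk_rho.append(sec.peak_rho[b, k])
    return DebranchedPath(frames=np.array(frames, int),
                          intervals=np.array(intervals, int),
                          peak_idx=np.array(pk_idx, int),
                          peak_rho=np.array(pk_rho, float),
                          total_distance=float(dist[bg.sink]),
                          ambiguous=ambiguous)


# --------------------------------------------------------------------------
# refinement

def refine_axial(rho_row: np.ndarray,
                 z_grid: np.ndarray,
                 interval: tuple[int, int],
                 peak_idx: int | None = None,
                 window: int = 3,
                 z_step: float | None = None) -> tuple[float, dict]:
    """Sub-grid peak of the correlation along z within the winning branch.

    A polynomial is fitted to the correlation samples of the branch within
    ``window`` grid points of the branch peak; its constrained argmax is
    the refined height.  Degree: ``min(4, n-1)`` on fine grids
    (z_step <= 5 nm), ``min(2, n-1)`` otherwise; a single-point branch is
    returned unrefined and a flat window falls back to its center.
    """
    lo, hi = int(interval[0]), int(interval[1])
    if z_step is None:
        z_step = float(z_grid[1] - z_grid[0]) if len(z_grid) > 1 else 1.0
    if peak_idx is None:
        peak_idx = lo + int(np.argmax(rho_row[lo:hi + 1]))
    flags = {"unrefined": False, "degenerate": False, "degree": 0}
    if hi == lo:
        flags["unrefined"] = True
        return float(z_grid[lo]), flags
    a = max(lo, peak_idx - window)
    b = min(hi, peak_idx + window)
    z = np.asarray(z_grid[a:b + 1], dtype=float)
    y = np.asarray(rho_row[a:b + 1], dtype=float)
    if np.ptp(y) == 0.0:
        flags["degenerate"] = True
        return float(0.5 * (z[0] + z[-1])), flags
    n = z.size
    degree = min(4, n - 1) if z_step <= 5.0 else min(2, n - 1)
    flags["degree"] = degree
    zc = (z - z.mean()) / max(np.ptp(z), 1.0)
    coeffs = np.polyfit(zc, y, degree)
    dcoeffs = np.polyder(coeffs)
    crit = np.roots(dcoeffs)
    crit = crit[np.isreal(crit)].real
    crit = crit[(crit >= zc[0]) & (crit <= zc[-1])]
    candidates = np.concatenate((crit, [zc[0], zc[-1]]))
    vals = np.polyval(coeffs, candidates)
    best = candidates[int(np.argmax(vals))]
    return float(best * max(np.ptp(z), 1.0) + z.mean()), flags


@dataclass
class AxialTrack:
    """Refined per-frame axial positions with tracking diagnostics."""

    frames: np.ndarray
    z_nm: np.ndarray              # NaN where the selected region is absent
    peak_rho: np.ndarray
    branch_id: np.ndarray         # -1 where absent
    segment_id: np.ndarray        # -1 where absent
    degree_used: np.ndarray
    ambiguous_segments: list = field(default_factory=list)


def track_axial(profiles: RadialProfileSeries,
                model: RadialModelStack,
                threshold: float = 0.0,
                refine_window: int = 3) -> AxialTrack:
    """Full axial pipeline: correlation map -> region -> graph -> refine."""
    cmap = correlation_map(profiles, model)
    labeling = label_regions(cmap, threshold)
    graphs = build_branch_graph(cmap, labeling.selected_mask())
    n = cmap.rho.shape[0]
    z = np.full(n, np.nan)
    pk = np.full(n, np.nan)
    branch = np.full(n, -1, int)
    segment = np.full(n, -1, int)
    degree = np.zeros(n, int)
    ambiguous = []
    rho = np.asarray(cmap.rho, dtype=np.float64)
    for s_id, bg in enumerate(graphs):
        path = shortest_path_debranch(bg)
        if path.ambiguous:
            ambiguous.append(s_id)
        for f, (lo, hi), p in zip(path.frames, path.intervals, path.peak_idx):
            z_ref, flags = refine_axial(rho[f], cmap.z_grid, (lo, hi),
                                        peak_idx=int(p), window=refine_window,
                                        z_step=cmap.z_step)
            z[f] = z_ref
            pk[f] = rho[f, p]
            branch[f] = p
            segment[f] = s_id
            degree[f] = flags["degree"]
    return AxialTrack(frames=np.asarray(profiles.frames), z_nm=z, peak_rho=pk,
                      branch_id=branch, segment_id=segment,
                      degree_used=degree, ambiguous_segments=ambiguous)
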