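"""Centerline extraction from binary vessel masks.

Centerlines are found as minimal-cost paths on the 26-connected voxel
graph of the vessel interior.  Edge costs are the physical step length
divided by ``1 + D`` where D is the Euclidean distance map (mm) at the
step's target voxel — a standard medialness weighting that pulls the
path onto the lumen axis, where the distance map is largest.  The voxel
path is then resampled at 0.5 x min(spacing) and smoothed with a 5-point
moving average, and tortuosity is computed on this smoothed, resampled
polyline (arc length over endpoint chord, minus one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .phantoms import LabeledMask

__all__ = [
    "CenterlineCurve",
    "BifurcationCenterlines",
    "distance_map",
    "minimal_cost_path",
    "extract_bifurcation",
    "tortuosity",
    "resample_polyline",
    "smooth_polyline",
]

SMOOTH_WINDOW = 5


@dataclass
class CenterlineCurve:
    """Ordered polyline (mm) for one vessel branch.

    Branch curves produced by :func:`extract_bifurcation` run from the
    bifurcation point toward the branch's free end.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("curve needs at least two 3D points")
        if self.chord == 0.0:
            raise ValueError("curve endpoints coincide")

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        return float(self.arc_lengths[-1])

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        return self.arc_length / self.chord - 1.0


@dataclass
class BifurcationCenterlines:
    cca: CenterlineCurve
    ica: CenterlineCurve
    eca: CenterlineCurve
    bifurcation_point: np.ndarray

    def branch(self, name: str) -> CenterlineCurve:
        return getattr(self, name)


def tortuosity(curve: CenterlineCurve | np.ndarray) -> float:
    """(L/D) - 1: arc length over endpoint chord, 0 for a straight segment."""
    if not isinstance(curve, CenterlineCurve):
        curve = CenterlineCurve(np.asarray(curve, float))
    return curve.tortuosity


def distance_map(mask: LabeledMask) -> np.ndarray:
    """Euclidean distance (mm) from each vessel voxel to the background.

    Anisotropic spacing aware; zero outside the vessel.  The value at a
    centerline point is the radius of the maximally inscribed sphere
    centred there.
    """
    if not np.any(mask.voxels):
        raise ValueError("mask is empty")
    return ndimage.distance_transform_edt(mask.voxels > 0, sampling=mask.spacing)


# ---------------------------------------------------------------------------
# voxel graph
# ---------------------------------------------------------------------------

def _neighbor_offsets() -> np.ndarray:
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return np.array(offs, int)


def _build_graph(mask: LabeledMask, dmap: np.ndarray):
    """Sparse directed graph over vessel voxels, 26-connectivity.

    Edge u->v weighs ||offset * spacing|| / (1 + dmap[v]).  Returns the
    CSR matrix, the (N,3) voxel indices and a flat-index -> node lookup.
    """
    vessel = mask.voxels > 0
    coords = np.argwhere(vessel)
    node_of = -np.ones(mask.voxels.shape, np.int64)
    node_of[tuple(coords.T)] = np.arange(len(coords))
    sp = np.asarray(mask.spacing)
    shape = np.asarray(mask.voxels.shape)

    rows, cols, data = [], [], []
    for off in _neighbor_offsets():
        tgt = coords + off
        ok = np.all((tgt >= 0) & (tgt < shape), axis=1)
        src_nodes = np.arange(len(coords))[ok]
        tgt_idx = tgt[ok]
        tgt_nodes = node_of[tuple(tgt_idx.T)]
        valid = tgt_nodes >= 0
        src_nodes, tgt_idx, tgt_nodes = src_nodes[valid], tgt_idx[valid], tgt_nodes[valid]
        step = float(np.linalg.norm(off * sp))
        rows.append(src_nodes)
        cols.append(tgt_nodes)
        data.append(step / (1.0 + dmap[tuple(tgt_idx.T)]))
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    )
    return graph, coords, node_of


def _nearest_vessel_node(mask: LabeledMask, node_of: np.ndarray, point, name: str) -> int:
    idx = np.rint(mask.world_to_index(point)[0]).astype(int)
    if np.any(idx < 0) or np.any(idx >= mask.voxels.shape) or mask.voxels[tuple(idx)] == 0:
        raise ValueError(f"point {name} at {np.asarray(point)} mm is outside the vessel")
    return int(node_of[tuple(idx)])


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (endpoints kept)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    return np.stack([np.interp(s, arc, pts[:, d]) for d in range(3)], axis=1)


def smooth_polyline(points: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Moving-average smoothing with edge replication (endpoints anchored)."""
    pts = np.asarray(points, float)
    if len(pts) <= window:
        return pts
    return ndimage.uniform_filter1d(pts, size=window, axis=0, mode="nearest")


def _postprocess(voxel_points: np.ndarray, spacing) -> CenterlineCurve:
    step = 0.5 * min(spacing)
    pts = resample_polyline(voxel_points, step)
    pts = smooth_polyline(pts)
    return CenterlineCurve(pts)


def _shortest_voxel_path(graph, coords, source: int, target: int, predecessors=None):
    if predecessors is None:
        dist, predecessors = dijkstra(graph, directed=True, indices=source,
                                      return_predecessors=True)
        if not np.isfinite(dist[target]):
            raise ValueError("endpoints are not connected within the vessel mask")
    path = [target]
    while path[-1] != source:
        prev = predecessors[path[-1]]
        if prev < 0:
            raise ValueError("endpoints are not connected within the vessel mask")
        path.append(int(prev))
    path.reverse()
    return path


def minimal_cost_path(mask: LabeledMask, a, b) -> CenterlineCurve:
    """Medialness-weighted shortest path between two points in the vessel.

    ``a`` and ``b`` are world coordinates (mm) strictly inside the vessel;
    the returned curve is resampled and smoothed and runs from a to b.
    """
    dmap = distance_map(mask)
    graph, coords, node_of = _build_graph(mask, dmap)
    na = _nearest_vessel_node(mask, node_of, a, "a")
    nb = _nearest_vessel_node(mask, node_of, b, "b")
    if na == nb:
        raise ValueError("endpoints a and b fall in the same voxel (degenerate path)")
    path = _shortest_voxel_path(graph, coords, na, nb)
    world = mask.index_to_world(coords[path])
    return _postprocess(world, mask.spacing)


def extract_bifurcation(mask: LabeledMask, markers: dict) -> BifurcationCenterlines:
    """Split a bifurcating vessel into three branch centerlines.

    ``markers`` maps ``'cca'``/``'ica'``/``'eca'`` to two world points
    (proximal, distal free end) inside the vessel.  Minimal-cost paths are
    traced from the CCA free end to each daughter free end; the
    bifurcation point is the last voxel the two paths share, and the
    branch curves are split there (each running from the bifurcation
    outward).
    """
    for key in ("cca", "ica", "eca"):
        if key not in markers or len(markers[key]) != 2:
            raise ValueError(f"markers must provide two points for {key!r}")
    dmap = distance_map(mask)
    graph, coords, node_of = _build_graph(mask, dmap)
    src = _nearest_vessel_node(mask, node_of, markers["cca"][1], "cca distal")
    n_ica = _nearest_vessel_node(mask, node_of, markers["ica"][1], "ica distal")
    n_eca = _nearest_vessel_node(mask, node_of, markers["eca"][1], "eca distal")

    dist, pred = dijkstra(graph, directed=True, indices=src, return_predecessors=True)
    for tgt, name in ((n_ica, "ica"), (n_eca, "eca")):
        if not np.isfinite(dist[tgt]):
            raise ValueError(f"{name} marker is not connected to the cca marker")
    path_i = _shortest_voxel_path(graph, coords, src, n_ica, predecessors=pred)
    path_e = _shortest_voxel_path(graph, coords, src, n_eca, predecessors=pred)

    # Work on resampled + smoothed paths: inside a wide lumen many
    # equal-cost voxel paths coexist, so the raw paths may run in adjacent
    # voxel lanes; smoothing removes the lane offsets before the junction
    # is located.
    step = 0.5 * min(mask.spacing)
    si = smooth_polyline(resample_polyline(mask.index_to_world(coords[path_i]), step))
    se = smooth_polyline(resample_polyline(mask.index_to_world(coords[path_e]), step))
    diag = float(np.linalg.norm(mask.spacing))
    d_ie, _ = cKDTree(se).query(si)
    d_ei, _ = cKDTree(si).query(se)
    close = np.flatnonzero(d_ie <= diag + 1e-9)
    if len(close) < 2 or close[0] > len(si) // 4:
        raise ValueError("paths to ICA and ECA share no common trunk; "
                         "markers are likely misplaced")
    i_split = int(close[-1])  # conservative end of the shared trunk

    # Refine: the proximity split overshoots the junction because both
    # paths hug the merged-lumen center for a while.  Fit a line to the
    # first clean (well separated) stretch of each daughter and take the
    # closest-approach midpoint of the two lines as the bifurcation point.
    bif = _daughter_line_intersection(si, d_ie, se, d_ei, diag, step)
    if bif is None or np.linalg.norm(bif - si[i_split]) > 4.0 * diag:
        bif = si[i_split]  # fall back to the last common point

    curves = {}
    trunk_end = int(np.argmin(np.linalg.norm(si - bif, axis=1)))
    trunk_end = min(trunk_end, i_split)
    if trunk_end < 1:
        raise ValueError("cca branch collapses to a single point; "
                         "markers are likely misplaced")
    cca_pts = np.vstack([bif[None, :], si[:trunk_end][::-1]])
    curves["cca"] = CenterlineCurve(resample_polyline(cca_pts, step))
    for name, pts, sep in (("ica", si, d_ie), ("eca", se, d_ei)):
        j0 = np.flatnonzero(sep > 1.5 * diag)
        j0 = int(j0[0]) if len(j0) else min(i_split + 1, len(pts) - 2)
        branch_pts = np.vstack([bif[None, :], pts[j0:]])
        if len(branch_pts) < 2:
            raise ValueError(f"{name} branch collapses to a single point; "
                             "markers are likely misplaced")
        curves[name] = CenterlineCurve(resample_polyline(branch_pts, step))
    return BifurcationCenterlines(
        cca=curves["cca"], ica=curves["ica"], eca=curves["eca"],
        bifurcation_point=bif,
    )


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through a point cloud: (centroid, unit direction)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0]


def _daughter_line_intersection(si, d_ie, se, d_ei, diag, step):
    """Closest-approach midpoint of lines fitted to the first well-separated
    stretch (~8 mm) of each daughter path; None if either stretch is absent
    or the lines are near parallel."""
    window = max(int(round(8.0 / step)), 4)
    segs = []
    for pts, sep in ((si, d_ie), (se, d_ei)):
        j = np.flatnonzero(sep > 1.5 * diag)
        if len(j) == 0 or j[0] + 4 > len(pts):
            return None
        segs.append(pts[j[0]: j[0] + window])
    (c1, v1), (c2, v2) = _fit_line(segs[0]), _fit_line(segs[1])
    # closest approach of two skew lines
    w0 = c1 - c2
    a, b, c = v1 @ v1, v1 @ v2, v2 @ v2
    d, e = v1 @ w0, v2 @ w0
    denom = a * c - b * b
    if denom < 1e-6:
        return None
    t1 = (b * e - c * d) / denom
    t2 = (a * e - b * d) / denom
    return 0.5 * (c1 + t1 * v1 + c2 + t2 * v2)
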