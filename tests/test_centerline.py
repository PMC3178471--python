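"""Centerline extraction: distance maps, minimal-cost paths, tortuosity."""

import heapq
import itertools
import math

import numpy as np
import pytest

from bifex import (
    CenterlineCurve,
    LabeledMask,
    distance_map,
    extract_bifurcation,
    make_tube_mask,
    minimal_cost_path,
    tortuosity,
)
from bifex.centerline import _build_graph


class TestDistanceMap:
    def test_cylinder_maximum_is_radius(self, straight_tube):
        mask, _ = straight_tube
        dm = distance_map(mask)
        assert dm.max() == pytest.approx(3.0, abs=0.5 * max(mask.spacing))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            distance_map(LabeledMask(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_single_voxel(self):
        vox = np.zeros((5, 5, 5), np.uint8)
        vox[2, 2, 2] = 1
        dm = distance_map(LabeledMask(vox, (2.0, 0.5, 0.5)))
        assert 0 < dm[2, 2, 2] <= min((2.0, 0.5, 0.5)) + 1e-12

    def test_anisotropic_sphere_against_brute_force(self):
        """EDT under (2, 0.5, 0.5) mm spacing vs exhaustive distance to the
        background voxel centers, at the center of a 4 mm sphere."""
        spacing = np.array([2.0, 0.5, 0.5])
        shape = (9, 33, 33)
        center = (np.array(shape) - 1) / 2 * spacing
        grids = np.meshgrid(*[spacing[d] * np.arange(shape[d]) for d in range(3)],
                            indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        inside = np.linalg.norm(pts - center, axis=1) <= 4.0
        mask = LabeledMask(inside.reshape(shape).astype(np.uint8), tuple(spacing))
        dm = distance_map(mask)
        brute = np.linalg.norm(pts[~inside] - center, axis=1).min()
        ci = tuple((np.array(shape) - 1) // 2)
        assert dm[ci] == pytest.approx(brute, abs=1e-9)
        assert dm[ci] == pytest.approx(4.0, abs=1.0)


class TestMinimalCostPath:
    def test_straight_cylinder_path_on_axis(self, straight_tube, straight_tube_centerline):
        mask, _ = straight_tube
        curve = straight_tube_centerline
        off_axis = np.linalg.norm(curve.points[:, 1:], axis=1)
        diag = np.linalg.norm(mask.spacing)
        assert off_axis.max() <= diag
        assert curve.tortuosity < 0.01

    def test_curved_tube_arc_length_recovered(self):
        mask, gt = make_tube_mask(3.0, 40.0, (0.5, 0.5, 0.5), curvature_amplitude=4.0)
        a, b = gt.markers["tube"]
        curve = minimal_cost_path(mask, a, b)
        true_l = gt.branches["tube"]["arc"][-1]
        assert curve.arc_length == pytest.approx(true_l, rel=0.02)

    def test_degenerate_endpoints_raise(self, straight_tube):
        mask, _ = straight_tube
        with pytest.raises(ValueError, match="same voxel"):
            minimal_cost_path(mask, [20.0, 0.0, 0.0], [20.1, 0.0, 0.0])

    def test_point_outside_vessel_named(self, straight_tube):
        mask, gt = straight_tube
        with pytest.raises(ValueError, match="b .*outside"):
            minimal_cost_path(mask, gt.markers["tube"][0], [20.0, 30.0, 30.0])

    def test_disconnected_components_raise(self):
        vox = np.zeros((30, 9, 9), np.uint8)
        vox[2:12, 2:7, 2:7] = 1
        vox[18:28, 2:7, 2:7] = 1
        mask = LabeledMask(vox, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="not connected"):
            minimal_cost_path(mask, [5.0, 4.0, 4.0], [22.0, 4.0, 4.0])

    def test_cost_matches_exhaustive_dijkstra_oracle(self):
        """On a small bent tube, the graph shortest-path distances equal an
        independently coded heapq Dijkstra over edge costs rebuilt from the
        definition (step length / (1 + distance map at target))."""
        vox = np.zeros((14, 14, 6), np.uint8)
        vox[1:13, 5:9, 1:5] = 1
        vox[5:9, 1:13, 1:5] = 1
        mask = LabeledMask(vox, (1.0, 0.7, 0.5))
        dm = distance_map(mask)
        graph, coords, node_of = _build_graph(mask, dm)

        # oracle: brute-force adjacency from the mask itself
        sp = np.array(mask.spacing)
        nodes = {tuple(c): i for i, c in enumerate(coords)}
        src = nodes[(1, 6, 2)]
        dist = {i: math.inf for i in range(len(coords))}
        dist[src] = 0.0
        heap = [(0.0, src)]
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            cu = coords[u]
            for off in offsets:
                t = tuple(cu + np.array(off))
                if t in nodes:
                    w = np.linalg.norm(np.array(off) * sp) / (1.0 + dm[t])
                    v = nodes[t]
                    if d + w < dist[v] - 1e-15:
                        dist[v] = d + w
                        heapq.heappush(heap, (d + w, v))

        from scipy.sparse.csgraph import dijkstra

        ours = dijkstra(graph, directed=True, indices=src)
        oracle = np.array([dist[i] for i in range(len(coords))])
        assert np.allclose(ours, oracle, atol=1e-10)


class TestTortuosity:
    def test_straight_segment_is_zero(self):
        pts = np.stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)], axis=1)
        assert tortuosity(pts) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_closed_form(self):
        theta = np.linspace(0, np.pi, 2001)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        assert tortuosity(pts) == pytest.approx(np.pi / 2 - 1, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0)
        base = tortuosity(pts)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + rng.normal(size=3) * 100
        assert tortuosity(moved) == pytest.approx(base, rel=1e-10)
        assert tortuosity(pts * 7.3) == pytest.approx(base, rel=1e-10)
        assert base >= 0.0

    def test_coincident_endpoints_raise(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        loop = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        loop[-1] = loop[0]  # exactly closed
        with pytest.raises(ValueError, match="coincide"):
            tortuosity(loop)


class TestExtractBifurcation:
    def test_bifurcation_point_near_truth(self, iso_extraction):
        spec, mask, gt, bc, _ = iso_extraction
        err = np.linalg.norm(bc.bifurcation_point - gt.bifurcation_point)
        assert err <= 1.5 * max(mask.spacing)

    def test_branch_curves_terminate_at_bifurcation(self, iso_extraction):
        _, _, _, bc, _ = iso_extraction
        for name in ("cca", "ica", "eca"):
            start = bc.branch(name).points[0]
            assert np.linalg.norm(start - bc.bifurcation_point) <= 1.0

    def test_branch_points_lie_in_labeled_branch(self, iso_extraction):
        """At least 90% of each curve's points carry that branch's label."""
        _, mask, _, bc, _ = iso_extraction
        from bifex.phantoms import BRANCH_LABELS

        for name in ("cca", "ica", "eca"):
            pts = bc.branch(name).points
            idx = np.rint(mask.world_to_index(pts)).astype(int)
            labels = mask.labels[tuple(idx.T)]
            frac = (labels == BRANCH_LABELS[name]).mean()
            assert frac >= 0.9, f"{name}: {frac:.2f}"

    def test_curves_inside_mask(self, iso_extraction):
        _, mask, _, bc, _ = iso_extraction
        for name in ("cca", "ica", "eca"):
            assert mask.contains(bc.branch(name).points).all()

    def test_straight_phantom_branches_have_low_tortuosity(self, iso_extraction):
        _, _, _, bc, _ = iso_extraction
        assert bc.ica.tortuosity < 0.02
        assert bc.eca.tortuosity < 0.02

    def test_disconnected_marker_raises(self, iso_phantom):
        _, mask, gt = iso_phantom
        markers = dict(gt.markers)
        markers["ica"] = (gt.markers["ica"][0], np.array([500.0, 500.0, 500.0]))
        with pytest.raises(ValueError, match="outside|not connected"):
            extract_bifurcation(mask, markers)

    def test_missing_branch_markers_raise(self, iso_phantom):
        _, mask, gt = iso_phantom
        markers = {k: v for k, v in gt.markers.items() if k != "eca"}
        with pytest.raises(ValueError, match="eca"):
            extract_bifurcation(mask, markers)


def test_curve_validation():
    with pytest.raises(ValueError):
        CenterlineCurve(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        CenterlineCurve(np.zeros((4, 3)))  # coincident endpoints
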