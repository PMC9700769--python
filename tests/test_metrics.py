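"""Graph conversion, enclosed regions, frame records, series comparison."""

import numpy as np
import pytest
from skimage.draw import circle_perimeter

from cordnet.skeleton import Skeleton, skeletonize
from cordnet.metrics import (
    FrameRecord,
    compare_series,
    enclosed_regions,
    frame_metrics,
    monotone_decrease_sign_test,
    skeleton_to_graph,
)


def spanning_tree_cycle_count(graph):
    """Independent cycle-space dimension oracle: edges minus union-find
    spanning-forest edges."""
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cycles = 0
    for u, v in graph.edges():
        ru, rv = find(u), find(v)
        if ru == rv:
            cycles += 1
        else:
            parent[ru] = rv
    return cycles


def ring_skeleton(radius, shape=(64, 64), center=(32, 32)):
    px = np.zeros(shape, dtype=bool)
    rr, cc = circle_perimeter(*center, radius)
    px[rr, cc] = True
    return Skeleton.from_pixels(px)


def theta_skeleton():
    """A ring with a chord: 2 junctions, 3 edges, 2 independent cycles."""
    sk = skeletonize(
        (lambda d2: (d2 <= 18**2) & (d2 >= 12**2))(
            sum(x**2 for x in np.mgrid[-32:32, -32:32])
        )
    )
    px = sk.pixels.copy()
    cols = np.nonzero(px[32])[0]
    px[32, cols.min() : cols.max() + 1] = True
    return skeletonize(px, prune_length=0)


class TestSkeletonToGraph:
    def test_straight_line(self):
        px = np.zeros((40, 40), dtype=bool)
        px[20, 5:35] = True
        g = skeleton_to_graph(Skeleton.from_pixels(px))
        assert g.n_nodes == 2 and g.n_edges == 1
        assert g.n_endpoints == 2
        assert g.total_length == pytest.approx(29.0)

    def test_pure_cycle_gets_anchor_and_self_loop(self):
        g = skeleton_to_graph(ring_skeleton(15))
        assert g.n_nodes == 1 and g.n_edges == 1
        kinds = [k for _, k in g.graph.nodes(data="kind")]
        assert kinds == ["cycle-anchor"]
        assert g.cyclomatic == 1

    def test_theta_two_junctions_three_edges(self):
        g = skeleton_to_graph(theta_skeleton())
        assert g.n_junctions == 2
        assert g.n_edges == 3
        assert g.cyclomatic == 2
        assert spanning_tree_cycle_count(g.graph) == 2

    def test_degree_sum_is_twice_edges(self):
        g = skeleton_to_graph(theta_skeleton())
        assert sum(d for _, d in g.graph.degree()) == 2 * g.n_edges

    def test_every_skeleton_pixel_covered_once(self):
        sk = theta_skeleton()
        g = skeleton_to_graph(sk)
        node_px = set()
        for _, pix in g.graph.nodes(data="pixels"):
            node_px.update(pix)
        chain_px = []
        for *_, d in g.graph.edges(data=True):
            chain_px.extend(p for p in d["path"] if p not in node_px)
        covered = node_px | set(chain_px)
        assert covered == {tuple(p) for p in np.argwhere(sk.pixels)}
        # interior chain pixels belong to exactly one edge path
        interior = [p for p in chain_px]
        assert len(interior) == len(set(interior))


class TestEnclosedRegions:
    def test_single_ring_area_close_to_analytic(self):
        regs = enclosed_regions(ring_skeleton(15))
        assert regs.count == 1
        assert regs.total_area == pytest.approx(np.pi * 15**2, rel=0.05)

    def test_border_touching_u_shape_encloses_nothing(self):
        px = np.zeros((32, 32), dtype=bool)
        px[0:28, 5] = True
        px[0:28, 25] = True
        px[27, 5:26] = True
        regs = enclosed_regions(Skeleton.from_pixels(px))
        assert regs.count == 0

    def test_grid_of_touching_squares(self):
        # walls 10 px apart sharing sides: four 9x9 interiors
        px = np.zeros((32, 32), dtype=bool)
        for x in (5, 15, 25):
            px[x, 5:26] = True
            px[5:26, x] = True
        regs = enclosed_regions(Skeleton.from_pixels(px))
        assert regs.count == 4
        assert [r.area_px for r in regs.regions] == [81, 81, 81, 81]

    def test_pixel_area_calibration_scales_areas(self):
        regs = enclosed_regions(ring_skeleton(10), pixel_area=0.25)
        assert regs.total_area == pytest.approx(
            enclosed_regions(ring_skeleton(10)).total_area * 0.25
        )

    def test_area_conservation(self):
        sk = theta_skeleton()
        regs = enclosed_regions(sk)
        h, w = sk.shape
        enclosed = sum(r.area_px for r in regs.regions)
        from scipy import ndimage as ndi

        lab, _ = ndi.label(~sk.pixels, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        border_labels = set(np.unique(np.concatenate(
            [lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
        border_bg = int(np.isin(lab, list(border_labels - {0})).sum())
        assert enclosed + border_bg + int(sk.pixels.sum()) == h * w

    def test_summary_recomputable_from_regions(self):
        regs = enclosed_regions(theta_skeleton())
        s = regs.summary()
        areas = [r.area for r in regs.regions]
        assert s["count"] == len(areas)
        assert s["total_area"] == pytest.approx(sum(areas))
        assert s["mean_area"] == pytest.approx(np.mean(areas))


class TestFrameMetrics:
    def test_empty_skeleton_all_zero(self):
        sk = Skeleton.from_pixels(np.zeros((32, 32), dtype=bool))
        rec = frame_metrics(sk, skeleton_to_graph(sk), enclosed_regions(sk))
        assert rec == FrameRecord.zero(0)

    def test_theta_loop_count_equals_cyclomatic(self):
        sk = theta_skeleton()
        rec = frame_metrics(sk, skeleton_to_graph(sk), enclosed_regions(sk))
        assert rec.loop_count == 2 and rec.cyclomatic == 2

    def test_frame_provenance_mismatch_rejected(self):
        sk = theta_skeleton()
        regs = enclosed_regions(sk, frame_id=3)
        with pytest.raises(ValueError):
            frame_metrics(sk, skeleton_to_graph(sk), regs, frame_id=1)

    def test_voronoi_loop_count_matches_ground_truth(self, noise_free_spec):
        from cordnet.preprocess import PreprocessParams, preprocess
        from cordnet.synthetic import generate_network

        img, truth = generate_network(noise_free_spec)
        sk = skeletonize(preprocess(img, PreprocessParams()).pixels)
        rec = frame_metrics(sk, skeleton_to_graph(sk), enclosed_regions(sk))
        assert rec.loop_count == truth.face_count


def _records(values):
    return [
        [FrameRecord(frame_id=i, loop_count=1, mean_area=v, median_area=v,
                     total_area=v, skeleton_length=0.0, n_junctions=0,
                     n_endpoints=0, n_components=1, cyclomatic=1)
         for i, v in enumerate(rep)]
        for rep in values
    ]


class TestCompareSeries:
    def test_identical_series_zero_difference(self):
        a = _records([[10.0, 20.0], [12.0, 18.0], [11.0, 22.0]])
        s = compare_series(a, a, n_boot=500, seed=1)
        assert np.allclose(s.difference, 0.0)
        assert s.terminal_ci[0] <= 0.0 <= s.terminal_ci[1]

    def test_replicate_order_irrelevant(self):
        vals = [[5.0], [9.0], [7.0]]
        a = _records(vals)
        b = _records(vals[::-1])
        s1 = compare_series(a, a, n_boot=300, seed=2)
        s2 = compare_series(b, b, n_boot=300, seed=2)
        assert s1.terminal_difference == s2.terminal_difference
        assert s1.terminal_ci == s2.terminal_ci

    def test_clear_separation_excludes_zero(self):
        rng = np.random.default_rng(0)
        a = _records([[100.0 + x] for x in rng.normal(0, 1, 15)])
        b = _records([[50.0 + x] for x in rng.normal(0, 1, 15)])
        s = compare_series(a, b, n_boot=1000, seed=3)
        assert s.terminal_ci[0] > 0

    def test_mismatched_lengths_rejected(self):
        a = _records([[1.0, 2.0], [1.0]])
        with pytest.raises(ValueError):
            compare_series(a, a)
        with pytest.raises(ValueError):
            compare_series([], [])


class TestSignTest:
    def test_strictly_decreasing_is_significant(self):
        vals = np.tile([4.0, 3.0, 2.0, 1.0], (10, 1))
        assert monotone_decrease_sign_test(vals) < 1e-6

    def test_flat_series_not_significant(self):
        vals = np.ones((10, 4))
        assert monotone_decrease_sign_test(vals) == 1.0

    def test_increasing_not_significant(self):
        vals = np.tile([1.0, 2.0, 3.0], (8, 1))
        assert monotone_decrease_sign_test(vals) > 0.5
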