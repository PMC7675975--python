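"""Neighbor graph, septum-width profiles, CDI and the septum reference."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

import cardiohist as ch
from cardiohist.septa import (
    NeighborEdge,
    build_neighbor_graph,
    compute_cdi,
    estimate_reference,
    fraction_dissociated,
    septum_width,
)
from cardiohist.wga import MyocyteRecord
from conftest import graph_from_widths, make_stripe_scene, map_detected_to_truth


class TestNeighborGraph:
    def test_two_side_by_side_cells_share_one_edge(self):
        _, _, labels, graph, _ = make_stripe_scene(4.0)
        assert len(graph.edges) == 1
        assert (graph.edges[0].id_a, graph.edges[0].id_b) == (1, 2)

    def test_interior_cell_of_hexagonal_lattice_has_six_neighbors(self):
        # 7 hexagonally packed cells: nearest-seed labeling of a center cell
        # surrounded by a ring of 6
        centers = [(60, 60)] + [
            (60 + 30 * np.cos(a), 60 + 30 * np.sin(a))
            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ]
        yy, xx = np.mgrid[:120, :120]
        d = np.stack([np.hypot(xx - cx, yy - cy) for cx, cy in centers])
        labels = d.argmin(axis=0) + 1
        records = [
            MyocyteRecord(i + 1, c, c, 500.0, 20.0, False, True)
            for i, c in enumerate(centers)
        ]
        graph = build_neighbor_graph(records, labels)
        assert len(graph.neighbors()[1]) == 6

    def test_mosaic_adjacency_is_subset_of_delaunay(self, clean_scene, clean_analysis):
        _, _, _, _, gt = clean_scene
        res = clean_analysis
        mapping = map_detected_to_truth(res.myocytes, gt)
        tri = Delaunay(gt.seeds_px)
        indptr, indices = tri.vertex_neighbor_vertices
        delaunay = set()
        for i in range(len(gt.seeds_px)):
            for j in indices[indptr[i]:indptr[i + 1]]:
                delaunay.add((min(i, j) + 1, max(i, j) + 1))
        for e in res.graph.edges:
            a, b = mapping[e.id_a], mapping[e.id_b]
            assert (min(a, b), max(a, b)) in delaunay
        # and it covers the ground-truth (gated) adjacency
        gt_pairs = {(e.id_a, e.id_b) for e in gt.edges}
        det_pairs = {
            (min(mapping[e.id_a], mapping[e.id_b]), max(mapping[e.id_a], mapping[e.id_b]))
            for e in res.graph.edges
        }
        overlap = len(gt_pairs & det_pairs) / len(gt_pairs)
        assert overlap >= 0.97

    def test_unknown_labels_rejected(self):
        labels = np.ones((64, 64), dtype=int)
        rec = MyocyteRecord(7, (1, 1), (1, 1), 10.0, 3.0, False, True)
        with pytest.raises(ValueError, match="label"):
            build_neighbor_graph([rec], labels)


class TestSeptumWidth:
    def test_exact_stripe_on_mask_profile(self):
        # hard-edged, pixel-aligned stripe: exactly 4 mask-true columns
        image, mask, labels, graph, edge = make_stripe_scene(
            4.0, center_x=48.5, soft=False
        )
        assert mask.grid[0, 40:60].sum() == 4
        w = septum_width(image, mask, labels, edge, graph, on_intensity=False)
        assert w == pytest.approx(4.0, abs=0.3)

    def test_zero_width_stripe_gives_zero(self):
        image, mask, labels, graph, edge = make_stripe_scene(0.0)
        assert septum_width(image, mask, labels, edge, graph) == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_randomized_stripe_widths_within_half_pixel(self, trial):
        rng = np.random.default_rng(trial)
        w_true = float(rng.uniform(1.0, 8.0))
        cx = 48.0 + float(rng.uniform(-5, 5))
        image, mask, labels, graph, edge = make_stripe_scene(w_true, center_x=cx)
        w = septum_width(image, mask, labels, edge, graph)
        assert w == pytest.approx(w_true, abs=0.5)

    def test_symmetric_in_edge_direction(self):
        image, mask, labels, graph, edge = make_stripe_scene(5.0)
        w1 = septum_width(image, mask, labels, edge, graph)
        flipped = NeighborEdge(edge.id_b, edge.id_a)
        w2 = septum_width(image, mask, labels, flipped, graph)
        assert w1 == pytest.approx(w2, abs=0.3)

    def test_mosaic_per_edge_error_on_clean_septa(self, clean_scene, clean_analysis):
        """On the noise-free mosaic, widths of cleanly crossed septa are
        recovered to sub-pixel accuracy and the image median to within 5%."""
        spec, _, _, _, gt = clean_scene
        res = clean_analysis
        mapping = map_detected_to_truth(res.myocytes, gt)
        truth = {(e.id_a, e.id_b): e.width_um for e in gt.edges if e.well_formed}
        px = spec.pixel_size_um
        errs = []
        for e in res.graph.edges:
            a, b = mapping.get(e.id_a), mapping.get(e.id_b)
            if a is None or b is None:
                continue
            key = (min(a, b), max(a, b))
            if key in truth:
                errs.append(abs(e.septum_width_um - truth[key]) / px)
        errs = np.array(errs)
        assert len(errs) > 100
        assert np.median(errs) < 0.25
        assert (errs <= 0.5).mean() >= 0.9
        med_gt = np.median([e.width_um for e in gt.edges])
        assert res.summary.median_septum_width_um == pytest.approx(med_gt, rel=0.05)


class TestCdi:
    def test_all_widths_below_threshold_gives_zero_cdi(self):
        g = graph_from_widths([(1, 2), (2, 3), (1, 3)], [1.0, 1.5, 2.0], 3)
        records, mean_cdi = compute_cdi(g, ch.ReferenceStats(3.0, 0.5))
        assert all(r.cdi == 0.0 for r in records)
        assert mean_cdi == 0.0

    def test_fraction_of_enhanced_neighbors(self):
        pairs = [(1, 2), (1, 3), (1, 4), (1, 5)]
        g = graph_from_widths(pairs, [10.0, 10.0, 1.0, 1.0], 5)
        records, _ = compute_cdi(g, ch.ReferenceStats(3.0, 0.5))
        center = next(r for r in records if r.myocyte_id == 1)
        assert center.n_neighbors == 4
        assert center.n_enhanced == 2
        assert center.cdi == pytest.approx(0.5)

    def test_isolated_node_flagged_undefined_and_excluded_from_mean(self):
        g = graph_from_widths([(1, 2)], [10.0], 3)  # node 3 isolated
        records, mean_cdi = compute_cdi(g, ch.ReferenceStats(3.0, 0.5))
        iso = next(r for r in records if r.myocyte_id == 3)
        assert iso.cdi is None
        assert mean_cdi == pytest.approx(1.0)

    def test_cdi_monotone_in_any_single_width(self):
        rng = np.random.default_rng(4)
        pairs = [(1, 2), (2, 3), (3, 4), (1, 4), (2, 4)]
        ref = ch.ReferenceStats(3.0, 0.5)
        for _ in range(20):
            widths = rng.uniform(1, 6, len(pairs))
            g = graph_from_widths(pairs, widths, 4)
            base = {r.myocyte_id: r.cdi for r in compute_cdi(g, ref)[0]}
            k = rng.integers(len(pairs))
            widths2 = widths.copy()
            widths2[k] += rng.uniform(0, 5)
            g2 = graph_from_widths(pairs, widths2, 4)
            bumped = {r.myocyte_id: r.cdi for r in compute_cdi(g2, ref)[0]}
            for node in base:
                assert bumped[node] >= base[node] - 1e-12

    def test_extreme_thresholds_saturate(self):
        pairs = [(1, 2), (2, 3)]
        g = graph_from_widths(pairs, [2.0, 4.0], 3)
        lo, _ = compute_cdi(g, ch.ReferenceStats(100.0, 0.0))
        assert all(r.cdi == 0.0 for r in lo)
        hi, _ = compute_cdi(g, ch.ReferenceStats(0.5, 0.0))
        assert all(r.cdi == 1.0 for r in hi)

    def test_fraction_dissociated_counts_cells(self):
        pairs = [(1, 2), (1, 3), (2, 3)]
        g = graph_from_widths(pairs, [10.0, 1.0, 1.0], 3)
        records, _ = compute_cdi(g, ch.ReferenceStats(3.0, 0.5))
        # node 1: 1/2 enhanced, node 2: 1/2, node 3: 0/2
        assert fraction_dissociated(records) == pytest.approx(2 / 3)


class TestReference:
    def test_constant_widths(self):
        g = graph_from_widths([(i, i + 1) for i in range(1, 12)], [3.0] * 11, 12)
        ref = estimate_reference([g])
        assert ref.mu_ref_um == pytest.approx(3.0)
        assert ref.sd_ref_um == pytest.approx(0.0)

    def test_two_point_sample_standard_deviation(self):
        widths = [2.0, 4.0] * 5
        g = graph_from_widths([(i, i + 1) for i in range(1, 11)], widths, 11)
        ref = estimate_reference([g])
        assert ref.mu_ref_um == pytest.approx(3.0)
        assert ref.sd_ref_um == pytest.approx(np.std(widths, ddof=1))

    def test_large_sample_recovers_distribution(self):
        rng = np.random.default_rng(5)
        n = 10_000
        widths = rng.normal(3.0, 0.5, n)
        pairs = [(i, i + 1) for i in range(1, n + 1)]
        g = graph_from_widths(pairs, widths, n + 1)
        ref = estimate_reference([g])
        assert ref.mu_ref_um == pytest.approx(3.0, abs=0.02)
        assert ref.sd_ref_um == pytest.approx(0.5, abs=0.02)

    def test_too_few_edges_rejected(self):
        g = graph_from_widths([(1, 2)], [3.0], 2)
        with pytest.raises(ValueError, match="10"):
            estimate_reference([g])
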