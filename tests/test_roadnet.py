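"""Tests for road simplification, sampling, aggregation and Jenks classing."""

import math

import numpy as np
import pandas as pd
import pytest

from greenview.roadnet import (
    RoadPolyline,
    aggregate_street_gvi,
    attach_nearest_svp,
    classify_natural_breaks,
    rasterize_fill_thin,
    sample_equidistant,
    vectorize_centerlines,
)
from greenview import synth

from _oracles import arc_point, jenks_bruteforce

OFF = 10_000.0  # keep coordinates clearly out of the lat/lon range


def road(coords, rid="r", width=10.0, rtype="T4"):
    return RoadPolyline(road_id=rid, coordinates=np.asarray(coords, float) + OFF,
                        width=width, road_type=rtype)


def no_2x2_block(occ):
    return not (occ[:-1, :-1] & occ[1:, :-1] & occ[:-1, 1:] & occ[1:, 1:]).any()


class TestRasterizeThin:
    def test_straight_road_gives_one_cell_wide_run(self):
        grid = rasterize_fill_thin([road([[0, 0], [1000, 0]])], cell_size=20.0)
        occ = grid.occupancy
        rows = np.nonzero(occ.any(axis=1))[0]
        assert len(rows) == 1
        assert occ[rows[0]].sum() >= 45
        assert no_2x2_block(occ)

    def test_plus_crossing_has_single_4_way_junction(self):
        roads = [road([[-500, 0], [500, 0]], "h"), road([[0, -500], [0, 500]], "v")]
        grid = rasterize_fill_thin(roads, cell_size=20.0)
        occ = grid.occupancy
        assert no_2x2_block(occ)
        # exactly one cell with 4 orthogonal-ish branches; connectivity intact
        from scipy.ndimage import label

        assert label(occ, structure=np.ones((3, 3)))[1] == 1
        centerlines = vectorize_centerlines(grid, source_roads=roads)
        assert len(centerlines) == 4  # the junction splits both roads

    def test_dual_carriageway_merges_to_single_centerline(self):
        roads = [
            road([[0, 0], [1000, 0]], "lane1", width=8.0),
            road([[0, 30], [1000, 30]], "lane2", width=12.0),
        ]
        grid = rasterize_fill_thin(roads, cell_size=20.0, fill_radius=1)
        from scipy.ndimage import label

        assert label(grid.occupancy, structure=np.ones((3, 3)))[1] == 1
        assert no_2x2_block(grid.occupancy)
        merged = vectorize_centerlines(grid, source_roads=roads)
        assert len(merged) == 1
        assert merged[0].width == pytest.approx(10.0)  # widths averaged

    def test_geographic_coordinates_rejected(self):
        geo = RoadPolyline("g", np.array([[116.3, 39.9], [116.4, 39.95]]), 10.0, "T4")
        with pytest.raises(ValueError, match="CRS|project"):
            rasterize_fill_thin([geo])

    def test_skeleton_thin_and_connected_on_synthetic_network(self):
        roads = synth.generate_network(synth.NetworkSpec(n_rings=2, n_radials=5, seed=7))
        grid = rasterize_fill_thin(roads)
        from scipy.ndimage import label

        assert no_2x2_block(grid.occupancy)
        assert label(grid.occupancy, structure=np.ones((3, 3)))[1] == 1


class TestVectorize:
    def test_straight_skeleton_traces_to_one_polyline(self):
        grid = rasterize_fill_thin([road([[0, 0], [1000, 0]])], cell_size=20.0)
        lines = vectorize_centerlines(grid)
        assert len(lines) == 1
        assert 940 <= lines[0].length <= 1000

    def test_l_shape_traces_through_corner(self):
        grid = rasterize_fill_thin([road([[0, 0], [600, 0], [600, 600]])], cell_size=20.0)
        lines = vectorize_centerlines(grid)
        assert len(lines) == 1  # corner is degree-2: single polyline
        assert sum(r.length for r in lines) == pytest.approx(1200, rel=0.08)

    def test_empty_grid_gives_empty_list(self):
        from greenview.roadnet import RasterGrid

        assert vectorize_centerlines(RasterGrid(np.zeros((5, 5), bool))) == []


class TestSampling:
    def test_exact_multiple_includes_both_endpoints(self):
        sites = sample_equidistant(road([[0, 0], [1000, 0]]), 100.0)
        assert len(sites) == 11
        assert [s.chainage for s in sites] == [pytest.approx(100.0 * k) for k in range(11)]

    def test_remainder_shorter_than_interval_dropped(self):
        sites = sample_equidistant(road([[0, 0], [999, 0]]), 100.0)
        assert len(sites) == 10
        assert sites[-1].chainage == pytest.approx(900.0)

    def test_zero_length_road_single_site(self):
        r = RoadPolyline("z", np.array([[OFF, OFF], [OFF, OFF]]), 5.0, "T5")
        sites = sample_equidistant(r, 100.0)
        assert len(sites) == 1 and sites[0].chainage == 0.0

    def test_zigzag_coordinates_match_arc_walk_oracle(self, rng):
        coords = np.cumsum(rng.uniform(-80, 120, size=(12, 2)), axis=0) + OFF
        r = RoadPolyline("zig", coords, 6.0, "T5")
        sites = sample_equidistant(r, 50.0)
        assert len(sites) == math.floor(r.length / 50.0) + 1
        for s in sites:
            ox, oy = arc_point(coords, s.chainage)
            assert s.coordinate[0] == pytest.approx(ox, abs=1e-6)
            assert s.coordinate[1] == pytest.approx(oy, abs=1e-6)

    def test_site_count_formula_over_seeded_roads(self, rng):
        for _ in range(40):
            n_vert = int(rng.integers(2, 8))
            coords = np.cumsum(rng.uniform(-200, 300, size=(n_vert, 2)), axis=0) + OFF
            r = RoadPolyline("x", coords, 6.0, "T5")
            sites = sample_equidistant(r, 100.0)
            assert len(sites) == math.floor(r.length / 100.0 + 1e-9) + 1

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            sample_equidistant(road([[0, 0], [10, 0]]), 0.0)


class TestAttachNearest:
    def test_within_radius_matched_inclusive_at_boundary(self):
        sites = sample_equidistant(road([[0, 0], [0.1, 0]]), 100.0)
        assert attach_nearest_svp(sites, np.array([[OFF + 10.0, OFF]]))[0] == 0
        assert attach_nearest_svp(sites, np.array([[OFF + 50.0, OFF]]))[0] == 0
        assert attach_nearest_svp(sites, np.array([[OFF + 51.0, OFF]]))[0] is None

    def test_matches_exhaustive_scan(self, rng):
        pts = rng.uniform(0, 500, size=(60, 2)) + OFF
        svp = rng.uniform(0, 500, size=(40, 2)) + OFF
        sites = [
            type("S", (), {"site_id": i, "coordinate": tuple(p)})() for i, p in enumerate(pts)
        ]
        got = attach_nearest_svp(sites, svp, max_radius=50.0)
        for i, p in enumerate(pts):
            d = np.hypot(*(svp - p).T)
            expected = int(d.argmin()) if d.min() <= 50.0 else None
            assert got[i] == expected


class TestAggregate:
    def test_single_road_mean(self):
        r = road([[0, 0], [300, 0]], "a")
        table = pd.DataFrame({"road_id": ["a"] * 3, "gvi": [0.1, 0.2, 0.3]})
        recs = aggregate_street_gvi(table, [r], classify=False)
        assert len(recs) == 1
        assert recs[0].mean_gvi == pytest.approx(0.2)
        assert recs[0].n_sites == 3

    def test_grouping_independent_between_roads(self):
        ra, rb = road([[0, 0], [100, 0]], "a"), road([[0, 50], [100, 50]], "b")
        table = pd.DataFrame({"road_id": ["a", "b", "a", "b"], "gvi": [0.1, 0.5, 0.3, 0.7]})
        recs = {r.road_id: r for r in aggregate_street_gvi(table, [ra, rb], classify=False)}
        assert recs["a"].mean_gvi == pytest.approx(0.2)
        assert recs["b"].mean_gvi == pytest.approx(0.6)

    def test_mass_conservation_on_seeded_tables(self, rng):
        road_ids = rng.integers(0, 40, size=500)
        gvi = rng.uniform(0, 1, size=500)
        table = pd.DataFrame({"road_id": road_ids, "gvi": gvi})
        roads = [road([[0, i * 10], [100, i * 10]], i) for i in range(40)]
        recs = aggregate_street_gvi(table, roads, classify=False)
        total = sum(r.mean_gvi * r.n_sites for r in recs)
        assert total == pytest.approx(gvi.sum(), abs=1e-9)
        # spot-check against an independent group-by
        for rid in set(road_ids):
            expect = gvi[road_ids == rid].mean()
            got = next(r.mean_gvi for r in recs if r.road_id == rid)
            assert got == pytest.approx(expect, abs=1e-12)


class TestJenks:
    def test_obvious_gap(self):
        edges, labels = classify_natural_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert edges[1] == 3
        assert labels == ["class_1"] * 3 + ["class_2"] * 3

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_equals_exhaustive_partition_minimizer(self, seed, k):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, size=int(rng.integers(k + 1, 13)))
        if len(np.unique(values)) < k:
            pytest.skip("degenerate draw")
        edges, labels = classify_natural_breaks(values, k=k)
        best_cost, best_edges = jenks_bruteforce(values, k)
        v = np.sort(values)
        cost = 0.0
        lab_order = sorted(set(labels), key=labels.index)
        for c in range(k):
            members = values[[lab == f"class_{c+1}" for lab in labels]]
            cost += ((members - members.mean()) ** 2).sum() if len(members) else 0.0
        assert cost == pytest.approx(best_cost, abs=1e-9)

    def test_five_class_labels_ascending(self, rng):
        values = rng.uniform(0, 1, 50)
        edges, labels = classify_natural_breaks(values, k=5)
        order = ["very_low", "low", "medium", "high", "very_high"]
        # class means must ascend with the labels
        means = [values[[lab == name for lab in labels]].mean() for name in order]
        assert all(a < b for a, b in zip(means, means[1:]))
        assert list(edges) == sorted(edges)

    def test_invariant_to_input_ordering(self, rng):
        values = rng.uniform(0, 1, 20)
        e1, _ = classify_natural_breaks(values, k=4)
        e2, _ = classify_natural_breaks(values[::-1], k=4)
        assert np.allclose(e1, e2)

    def test_beats_equal_interval_classing(self, rng):
        values = np.concatenate([rng.normal(0.1, 0.01, 20), rng.normal(0.8, 0.01, 20)])
        edges, labels = classify_natural_breaks(values, k=2)
        jenks_ssd = sum(
            ((values[[lab == name for lab in labels]]
              - values[[lab == name for lab in labels]].mean()) ** 2).sum()
            for name in set(labels)
        )
        mid = (values.min() + values.max()) / 2
        eq = values <= mid
        eq_ssd = ((values[eq] - values[eq].mean()) ** 2).sum() + (
            (values[~eq] - values[~eq].mean()) ** 2
        ).sum()
        assert jenks_ssd <= eq_ssd + 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            classify_natural_breaks([0.5] * 10, k=5)
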