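"""Nearest-neighbor, dilation-ratio and hull-distance statistics."""
import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import pharmstorm as ps
from pharmstorm import ValidationError


def _table(x, y):
    return ps.LocalizationTable.from_arrays(x, y)


class TestNND:
    def test_three_four_five(self):
        np.testing.assert_allclose(ps.nnd(_table([0, 3], [0, 4])), [5.0, 5.0])

    def test_collinear(self):
        np.testing.assert_allclose(ps.nnd(_table([0, 10, 25], [0, 0, 0])), [10, 10, 15])

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            ps.nnd(_table([0], [0]))

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, size=(500, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(ps.nnd(_table(*pts.T)), d.min(axis=1))

    def test_csr_closed_form_cdf(self):
        """Under CSR the NND CDF approaches 1 - exp(-lambda*pi*r^2)."""
        lam = 100.0  # per um2
        roi = ps.PolygonROI.rectangle(0, 0, 10_000, 10_000)
        table = ps.randomize_lps(10_000, roi, seed=1)
        dist = ps.nnd(table)
        margin = 3 * np.median(dist)
        x, y = table.coords.T
        interior = (x > margin) & (x < 10_000 - margin) & (y > margin) & (y < 10_000 - margin)
        d = np.sort(dist[interior])
        ecdf = np.arange(1, len(d) + 1) / len(d)
        assert np.max(np.abs(ecdf - ps.csr_nnd_cdf(d, lam))) < 0.03


class TestRandomizeLPs:
    def test_points_inside_region_and_reproducible(self, square_roi):
        a = ps.randomize_lps(500, square_roi, seed=2)
        b = ps.randomize_lps(500, square_roi, seed=2)
        assert square_roi.contains(*a.coords.T).all()
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_zero_points(self, square_roi):
        assert len(ps.randomize_lps(0, square_roi, seed=0)) == 0

    def test_mean_position_near_centroid(self, square_roi):
        means = np.array([ps.randomize_lps(400, square_roi, seed=s).coords.mean(0) for s in range(50)])
        # CLT: sd of one mean is 10000/sqrt(12)/sqrt(400) per axis
        se = 10_000 / np.sqrt(12) / np.sqrt(400) / np.sqrt(50)
        assert np.all(np.abs(means.mean(0) - 5000) < 4 * se)

    def test_uniform_over_mask_domain(self, disk_masks):
        t = ps.randomize_lps(300, disk_masks[0], seed=3)
        assert disk_masks[0].contains(*t.coords.T).all()


class TestCompareCDFs:
    def test_identical_samples(self):
        d, p = ps.compare_cdfs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ps.compare_cdfs([], [1.0])

    def test_type_one_error_calibration(self):
        rejections = 0
        n_pairs = 200
        rng = np.random.default_rng(4)
        for _ in range(n_pairs):
            _, p = ps.compare_cdfs(rng.uniform(0, 1, 200), rng.uniform(0, 1, 200))
            rejections += p < 0.05
        assert rejections / n_pairs < 0.10  # ~ alpha


class TestPrepareStructureMask:
    def test_block_upsampling(self):
        raster = np.zeros((4, 4), np.uint16)
        raster[1, 2] = 100
        mask = ps.prepare_structure_mask(raster, threshold=50)
        assert mask.pixel_size == 10.0
        assert mask.pixels.sum() == 64  # one 80 nm pixel -> 8x8 block
        assert mask.pixels[8:16, 16:24].all()

    def test_area_preserved_by_resampling(self):
        rng = np.random.default_rng(5)
        raster = rng.integers(0, 1000, (16, 16))
        mask = ps.prepare_structure_mask(raster, threshold=500)
        assert mask.area_nm2 == pytest.approx((raster >= 500).sum() * 80.0**2)

    def test_threshold_above_max_gives_empty_then_downstream_error(self):
        raster = np.full((4, 4), 10, np.uint8)
        mask = ps.prepare_structure_mask(raster, threshold=11)
        assert not mask.pixels.any()
        with pytest.raises(ValidationError):
            ps.structure_density_ratio(_table([0], [0]), mask)

    def test_threshold_outside_range_rejected(self):
        raster = np.full((4, 4), 10, np.uint8)
        with pytest.raises(ValidationError):
            ps.prepare_structure_mask(raster, threshold=100)


class TestDilation:
    def test_matches_iterated_3x3_dilation(self):
        rng = np.random.default_rng(6)
        pixels = rng.random((80, 80)) < 0.02
        mask = ps.StructureMask(pixels, pixel_size=10.0)
        for n in (1, 5, 17):
            expected = ndimage.binary_dilation(pixels, np.ones((3, 3), bool), iterations=n)
            assert np.array_equal(ps.dilate_mask(mask, n).pixels, expected)

    def test_area_monotone_in_iterations(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        areas = [ps.dilate_mask(mask, n).area_nm2 for n in (0, 10, 25, 50, 100)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))


class TestStructureDensityRatio:
    def test_all_on_structure_gives_area_ratio(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        neighborhood = ps.dilate_mask(mask, 50)
        t = ps.randomize_lps(400, mask, seed=7)
        res = ps.structure_density_ratio(t, mask, seed=8)
        assert res.ratio == pytest.approx(neighborhood.area_um2 / mask.area_um2)

    def test_off_structure_gives_ratio_below_one(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        roi = ps.PolygonROI.rectangle(0, 0, 4000, 4000)
        scene = ps.place_molecules(disk_masks, roi, 0.0, 300.0, seed=9)
        t = _table(scene.molecules["x_nm"], scene.molecules["y_nm"])
        assert ps.structure_density_ratio(t, mask, seed=10).ratio < 1.0

    def test_invariant_to_lp_count_scaling(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        roi = ps.PolygonROI.rectangle(0, 0, 4000, 4000)
        t = ps.randomize_lps(2000, roi, seed=11)
        doubled = _table(np.tile(t.data["x_nm"], 2), np.tile(t.data["y_nm"], 2))
        r1 = ps.structure_density_ratio(t, mask, randomized_control=False).ratio
        r2 = ps.structure_density_ratio(doubled, mask, randomized_control=False).ratio
        assert r2 == pytest.approx(r1)

    def test_direction_tracks_generator_enrichment(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        roi = ps.PolygonROI.rectangle(0, 0, 4000, 4000)
        ratios = {"enriched": [], "avoiding": []}
        for s in range(8):
            for name, (d_on, d_off) in {"enriched": (600.0, 100.0), "avoiding": (50.0, 400.0)}.items():
                scene = ps.place_molecules(disk_masks, roi, d_on, d_off, seed=20 + s)
                t = _table(scene.molecules["x_nm"], scene.molecules["y_nm"])
                ratios[name].append(ps.structure_density_ratio(t, mask, randomized_control=False).ratio)
        assert np.median(ratios["enriched"]) > 1.0
        assert np.median(ratios["avoiding"]) < 1.0

    def test_randomized_control_near_one(self, disk_masks):
        mask = ps.union_masks(disk_masks)
        roi = ps.PolygonROI.rectangle(0, 0, 4000, 4000)
        scene = ps.place_molecules(disk_masks, roi, 600.0, 100.0, seed=12)
        t = _table(scene.molecules["x_nm"], scene.molecules["y_nm"])
        controls = [
            ps.structure_density_ratio(t, mask, seed=s).randomized_ratio for s in range(12)
        ]
        assert np.median(controls) == pytest.approx(1.0, abs=0.1)

    def test_empty_mask_rejected(self):
        mask = ps.StructureMask(np.zeros((10, 10), bool), 10.0)
        with pytest.raises(ValidationError):
            ps.structure_density_ratio(_table([1], [1]), mask)


class TestMedianTest:
    def test_all_ones_degenerate(self):
        assert ps.test_median_vs_one([1.0] * 12) == 1.0

    def test_all_twos_significant_at_n12(self):
        assert ps.test_median_vs_one([2.0] * 12) < 0.05

    def test_symmetric_sample_not_significant(self):
        rng = np.random.default_rng(13)
        rejections = sum(
            ps.test_median_vs_one(1.0 + rng.normal(0, 0.2, 12)) < 0.05 for _ in range(100)
        )
        assert rejections <= 12  # close to the nominal 5 of 100

    def test_too_few_ratios_rejected(self):
        with pytest.raises(ValidationError):
            ps.test_median_vs_one([1.0, 2.0])


class TestConvexHulls:
    def test_square_hull(self):
        t = _table([0, 100, 100, 0, 50], [0, 0, 100, 100, 50])
        fit = ps.fit_convex_hulls(t, [ps.PolygonROI.rectangle(-10, -10, 110, 110)])
        assert len(fit.hulls) == 1 and not fit.excluded
        assert len(fit.hulls[0].vertices) == 4
        assert fit.hulls[0].area_nm2 == pytest.approx(100 * 100)

    def test_underpopulated_bouton_excluded(self):
        t = _table([0, 10], [0, 10])
        fit = ps.fit_convex_hulls(t, [ps.PolygonROI.rectangle(-10, -10, 20, 20)])
        assert fit.hulls == [] and fit.excluded == [0]

    def test_collinear_points_excluded(self):
        t = _table([0, 10, 20, 30], [0, 0, 0, 0])
        fit = ps.fit_convex_hulls(t, [ps.PolygonROI.rectangle(-10, -10, 40, 10)])
        assert fit.excluded == [0]

    def test_hull_contains_all_points(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(500, 100, size=(1000, 2))
        t = _table(*pts.T)
        fit = ps.fit_convex_hulls(t, [ps.PolygonROI.rectangle(-1000, -1000, 2000, 2000)])
        hull = fit.hulls[0]
        assert hull.contains(*pts.T).all()
        # hull vertices are a subset of the input LPs
        for v in hull.vertices:
            assert np.any(np.all(np.isclose(pts, v), axis=1))


class TestHullDistances:
    SQUARE = ps.PolygonROI.rectangle(0, 0, 100, 100)

    def test_outside_point_distance(self):
        res = ps.hull_surface_distances(_table([150], [50]), [self.SQUARE], cutoff=1000)
        assert res.distances[0] == pytest.approx(50.0)

    def test_inside_point_distance_zero(self):
        res = ps.hull_surface_distances(_table([50], [50]), [self.SQUARE])
        assert res.distances[0] == 0.0

    def test_cutoff_drops_remote_points(self):
        res = ps.hull_surface_distances(_table([150, 5000], [50, 50]), [self.SQUARE], cutoff=1000)
        assert len(res.distances) == 1 and res.n_input == 2

    def test_matches_dense_edge_sampling_oracle(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(500, 150, size=(40, 2))
        hull = ps.fit_convex_hulls(
            _table(*pts.T), [ps.PolygonROI.rectangle(-1000, -1000, 2000, 2000)]
        ).hulls[0]
        queries = rng.uniform(-500, 1500, size=(1000, 2))
        res = ps.hull_surface_distances(_table(*queries.T), [hull], cutoff=np.inf)
        # oracle: min distance to edge points sampled every 0.1 nm, 0 inside
        verts = hull.vertices
        samples = []
        for a, b in zip(verts, np.roll(verts, -1, axis=0)):
            n = max(2, int(np.linalg.norm(b - a) / 0.1))
            samples.append(a + np.linspace(0, 1, n)[:, None] * (b - a))
        samples = np.vstack(samples)
        from scipy.spatial import cKDTree

        oracle = cKDTree(samples).query(queries)[0]
        inside = shapely.intersects_xy(hull.polygon, queries[:, 0], queries[:, 1])
        oracle[inside] = 0.0
        assert np.max(np.abs(res.distances - oracle)) <= 0.2

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
        theta=st.floats(0, 2 * np.pi),
    )
    def test_translation_rotation_invariance(self, dx, dy, theta):
        rng = np.random.default_rng(16)
        pts = rng.uniform(0, 200, size=(12, 2))
        queries = rng.uniform(-200, 400, size=(30, 2))
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([dx, dy])

        def dists(p, q):
            hull = ps.fit_convex_hulls(
                _table(*p.T), [ps.PolygonROI(np.array([[-1e5, -1e5], [1e5, -1e5], [1e5, 1e5], [-1e5, 1e5]]))]
            ).hulls[0]
            return ps.hull_surface_distances(_table(*q.T), [hull], cutoff=np.inf).distances

        d0 = dists(pts, queries)
        d1 = dists(pts @ rot.T + shift, queries @ rot.T + shift)
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_null_comparison_for_csr_drug(self, square_roi):
        rng = np.random.default_rng(17)
        pts = rng.normal(5000, 400, size=(60, 2))
        hull = ps.fit_convex_hulls(_table(*pts.T), [square_roi]).hulls[0]
        drug = ps.randomize_lps(2000, square_roi, seed=18)
        res = ps.hull_surface_distances(drug, [hull], null_region=square_roi, seed=19)
        assert res.p_value is not None and res.p_value > 0.001
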