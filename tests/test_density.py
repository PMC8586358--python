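"""LP counting, windowing, background correction and ratio normalization."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pharmstorm as ps
from pharmstorm import ValidationError
from conftest import point_in_polygon_crossing

GEOM = ps.CameraGeometry(pixel_size=160.0, sensor_width=256, sensor_height=256)


def _table(x, y, geometry=GEOM):
    return ps.LocalizationTable.from_arrays(x, y, geometry=geometry)


class TestInnerWindow:
    @pytest.mark.parametrize("inner_px,area", [(64, 104.86), (32, 26.21), (128, 419.43)])
    def test_window_areas(self, inner_px, area):
        window = ps.inner_window(GEOM, inner_px)
        assert round(window.area_um2, 2) == area

    def test_crop_identity_at_full_sensor(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(0, GEOM.field_width_nm, 500), rng.uniform(0, GEOM.field_height_nm, 500))
        cropped, window = ps.crop_inner(t, 256)
        assert len(cropped) == 500
        assert window.area_um2 == pytest.approx((256 * 0.16) ** 2)

    def test_crop_keeps_only_window_lps(self):
        # sensor center is at 20480 nm; the 64 px window spans 15360..25600 nm
        t = _table([100.0, 16000.0, 25600.0], [16000.0, 16000.0, 16000.0])
        cropped, _ = ps.crop_inner(t, 64)
        assert cropped.data["x_nm"].tolist() == [16000.0]

    def test_oversized_window_rejected(self):
        with pytest.raises(ValidationError):
            ps.inner_window(GEOM, 512)


class TestCounting:
    def test_count_inside_and_boundary(self):
        roi = ps.PolygonROI.rectangle(0, 0, 1000, 1000)
        t = _table([10, 500, 999, 0, 1500, -5, 2000, 500], [10, 500, 999, 0, 1500, 500, 2000, 1000])
        # 5 inside/boundary (closed region), 3 outside
        assert ps.count_in_roi(t, roi) == 5

    def test_partition_additivity(self):
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(0, 2000, 5000), rng.uniform(0, 1000, 5000))
        whole = ps.PolygonROI.rectangle(0, 0, 2000, 1000)
        left = ps.PolygonROI.rectangle(0, 0, 1000, 1000)
        right = ps.PolygonROI.rectangle(1000, 0, 2000, 1000)
        n_l, n_r, n_w = (ps.count_in_roi(t, r) for r in (left, right, whole))
        # the shared edge x=1000 belongs to both closed halves
        on_edge = int(np.sum(t.data["x_nm"] == 1000.0))
        assert n_l + n_r == n_w + on_edge

    def test_count_matches_crossing_number_oracle(self):
        rng = np.random.default_rng(2)
        verts = np.array([[0, 0], [1200, 300], [900, 1100], [300, 900]], float)
        roi = ps.PolygonROI(verts)
        x = rng.uniform(-200, 1400, 10_000)
        y = rng.uniform(-200, 1400, 10_000)
        expected = sum(point_in_polygon_crossing(verts, xi, yi) for xi, yi in zip(x, y))
        assert ps.count_in_roi(_table(x, y), roi) == expected


class TestDensity:
    def test_density_is_count_over_area(self):
        window = ps.inner_window(GEOM, 32)
        x0, y0, _, _ = window.bounds
        rng = np.random.default_rng(3)
        t = _table(x0 + rng.uniform(0, 5120, 100), y0 + rng.uniform(0, 5120, 100))
        res = ps.density(t, window)
        assert res.count == 100
        assert res.density_per_um2 == pytest.approx(100 / 26.2144)

    def test_empty_table_zero_density(self):
        res = ps.density(_table([], []), ps.PolygonROI.rectangle(0, 0, 1000, 1000))
        assert res.count == 0 and res.density_per_um2 == 0.0

    def test_doubling_region_halves_density(self):
        t = _table([100, 200, 300], [100, 200, 300])
        small = ps.density(t, ps.PolygonROI.rectangle(0, 0, 1000, 1000))
        big = ps.density(t, ps.PolygonROI.rectangle(0, 0, 2000, 1000))
        assert big.density_per_um2 == pytest.approx(small.density_per_um2 / 2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(dx=st.floats(-1e5, 1e5), dy=st.floats(-1e5, 1e5))
    def test_translation_invariance(self, dx, dy):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0, 1000, 200), rng.uniform(0, 1000, 200)
        roi = ps.PolygonROI.rectangle(0, 0, 1000, 1000)
        shifted_roi = ps.PolygonROI.rectangle(dx, dy, 1000 + dx, 1000 + dy)
        d0 = ps.density(_table(x, y), roi).density_per_um2
        d1 = ps.density(_table(x + dx, y + dy), shifted_roi).density_per_um2
        assert d1 == pytest.approx(d0)

    def test_crop_then_density_consistency(self):
        rng = np.random.default_rng(5)
        t = _table(rng.uniform(0, GEOM.field_width_nm, 3000), rng.uniform(0, GEOM.field_height_nm, 3000))
        cropped, window = ps.crop_inner(t, 64)
        direct = ps.density(t, window)
        assert direct.count == len(cropped)
        assert direct.density_per_um2 == pytest.approx(len(cropped) / window.area_um2)


class TestBackgroundCorrection:
    @pytest.mark.parametrize(
        "signal,background,corrected,clamped",
        [(5.0, 2.0, 3.0, False), (2.0, 2.0, 0.0, False), (1.0, 2.0, 0.0, True)],
    )
    def test_subtraction_and_clamp(self, signal, background, corrected, clamped):
        res = ps.DensityResult(0, 1.0, signal)
        bg = ps.DensityResult(0, 1.0, background)
        out = ps.background_correct(res, bg)
        assert out.corrected_density_per_um2 == pytest.approx(corrected)
        assert out.clamped is clamped

    def test_corrected_density_unbiased_under_csr(self, square_roi):
        """signal + background minus matched background recovers the truth."""
        signal_d, bg_d = 8.0, 4.0
        estimates = []
        for s in range(100):
            rng = np.random.default_rng(s)
            sig = ps.render_blinks(
                ps.place_molecules([], square_roi, 0.0, signal_d, seed=rng),
                ps.BlinkModel(sigma_xy=0.0, lp_count_dist={1: 1.0}),
                background_rate=bg_d,
                seed=rng,
            )
            ctrl = ps.randomize_lps(rng.poisson(bg_d * square_roi.area_um2), square_roi, seed=rng)
            res = ps.background_correct(ps.density(sig, square_roi), ps.density(ctrl, square_roi))
            estimates.append(res.corrected_density_per_um2)
        assert np.mean(estimates) == pytest.approx(signal_d, rel=0.05)


class TestRatios:
    def test_plain_ratio(self):
        p = _table(np.zeros(200), np.zeros(200))
        i = _table(np.zeros(100), np.zeros(100))
        assert ps.pharmaco_immuno_ratio(p, i).ratio == pytest.approx(2.0)

    def test_zero_immuno_rejected(self):
        with pytest.raises(ValidationError):
            ps.pharmaco_immuno_ratio(_table([1], [1]), _table([], []))

    def test_vehicle_normalization_identity(self):
        vehicle_ratios = [1.5, 2.0, 2.5, 3.0]
        normalized = []
        for r in vehicle_ratios:
            p = _table(np.zeros(int(r * 100)), np.zeros(int(r * 100)))
            i = _table(np.zeros(100), np.zeros(100))
            normalized.append(
                ps.pharmaco_immuno_ratio(p, i, group_reference=vehicle_ratios).normalized_ratio
            )
        assert np.mean(normalized) == pytest.approx(1.0)

    def test_full_displacement_scenario(self, square_roi):
        """Antagonist pretreatment: drug channel carries only background."""
        rng = np.random.default_rng(7)
        immuno = ps.randomize_lps(800, square_roi, seed=rng)
        vehicle_ratios = []
        for s in range(4):
            pharmaco = ps.randomize_lps(1600, square_roi, seed=100 + s)
            vehicle_ratios.append(ps.pharmaco_immuno_ratio(pharmaco, immuno).ratio)
        displaced = ps.randomize_lps(40, square_roi, seed=8)  # background only
        res = ps.pharmaco_immuno_ratio(displaced, immuno, group_reference=vehicle_ratios)
        assert res.normalized_ratio < 0.1


class TestOccupancyCurve:
    def test_reference_is_100_percent(self):
        data = {10.0: [0.2, 0.3], 1000.0: [1.0, 1.2]}
        curve = ps.occupancy_curve(data, 1000.0)
        ref_row = curve[curve["concentration_nm"] == 1000.0].iloc[0]
        assert ref_row["occupancy_pct"] == pytest.approx(100.0)

    def test_zero_elsewhere(self):
        curve = ps.occupancy_curve({1.0: [0.0], 1000.0: [2.0]}, 1000.0)
        assert curve[curve["concentration_nm"] == 1.0]["occupancy_pct"].iloc[0] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            ps.occupancy_curve({1.0: [0.5]}, 1000.0)

    def test_one_site_occupancy_at_kd(self):
        """Noiseless one-site signal, referenced to 1 µM: occupancy at the
        Kd (123 nM) is 0.5/(1000/1123) ~ 56.2% of the reference signal."""
        kd = 123.0
        concs = [10.0, 123.0, 1000.0]
        data = {c: [c / (c + kd)] for c in concs}
        curve = ps.occupancy_curve(data, 1000.0)
        at_kd = curve[curve["concentration_nm"] == kd]["occupancy_pct"].iloc[0]
        assert at_kd == pytest.approx(56.15, abs=0.05)
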