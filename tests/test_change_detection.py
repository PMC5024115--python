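import datetime as dt

import numpy as np
import pytest

from reefwatch.change_detection import (
    DetectionConfig,
    IslandComponent,
    detect_new_islands,
    detect_shallow_water,
    fit_temporal_slope,
    island_components,
)
from reefwatch.series import DAYS_PER_YEAR
from tests.conftest import make_series

D0 = dt.date(2013, 1, 1)


def daily_dates(n, start=D0):
    return [start + dt.timedelta(days=i) for i in range(n)]


class TestShallowWater:
    def build(self, grid, red_values, cloud=None):
        dates = daily_dates(len(red_values))
        T = len(dates)
        red = np.stack([np.full(grid.shape, v, dtype=np.float32) for v in red_values])
        return make_series(grid, dates, {645: red}, cloud=cloud)

    def test_always_below_threshold(self, tiny_grid):
        series = self.build(tiny_grid, [0.004] * 25)
        mask = detect_shallow_water(series)
        assert not mask.any()

    def test_22_of_25_exceedances_is_shallow(self, tiny_grid):
        series = self.build(tiny_grid, [0.006] * 22 + [0.004] * 3)
        assert detect_shallow_water(series).all()

    def test_19_exceedances_is_not_shallow(self, tiny_grid):
        series = self.build(tiny_grid, [0.006] * 19 + [0.004] * 6)
        assert not detect_shallow_water(series).any()

    def test_cloudy_exceedances_do_not_count(self, tiny_grid):
        T = 25
        cloud = np.zeros((T, *tiny_grid.shape), dtype=bool)
        cloud[:3] = True  # 22 exceedances -> only 19 cloud-free
        series = self.build(tiny_grid, [0.006] * 22 + [0.004] * 3, cloud=cloud)
        assert not detect_shallow_water(series).any()

    def test_window_outside_series_errors(self, tiny_grid):
        series = self.build(tiny_grid, [0.006] * 25)
        with pytest.raises(ValueError, match="window"):
            detect_shallow_water(series, window=(D0, dt.date(2014, 1, 1)))

    def test_counting_oracle_random_series(self, tiny_grid):
        rng = np.random.default_rng(5)
        T = 60
        dates = daily_dates(T)
        red = rng.uniform(0.0, 0.01, (T, *tiny_grid.shape)).astype(np.float32)
        cloud = rng.random((T, *tiny_grid.shape)) < 0.3
        series = make_series(tiny_grid, dates, {645: red}, cloud=cloud)
        cfg = DetectionConfig(shallow_min_count=20)
        mask = detect_shallow_water(series, cfg)
        # brute-force per-pixel counting oracle
        expected = np.zeros(tiny_grid.shape, dtype=bool)
        for i in range(tiny_grid.ny):
            for j in range(tiny_grid.nx):
                n = sum(
                    1
                    for t in range(T)
                    if not cloud[t, i, j] and red[t, i, j] > cfg.shallow_threshold
                )
                expected[i, j] = n >= cfg.shallow_min_count
        assert np.array_equal(mask, expected)


class TestSlopeFit:
    def test_constant_series_slope_zero(self, tiny_grid):
        T = 20
        series = make_series(
            tiny_grid, daily_dates(T), {859: np.full((T, *tiny_grid.shape), 0.01, dtype=np.float32)}
        )
        slopes = fit_temporal_slope(series, min_valid_obs=2)
        np.testing.assert_allclose(slopes.slope, 0.0, atol=1e-9)

    def test_closed_form_three_points(self, tiny_grid):
        # values 0.02, 0.045, 0.07 at t = 0, 0.5, 1.0 years -> slope 0.05 / y
        half_year = round(DAYS_PER_YEAR / 2)
        dates = [D0, D0 + dt.timedelta(days=half_year), D0 + dt.timedelta(days=2 * half_year)]
        t = np.array([0.0, half_year, 2 * half_year]) / DAYS_PER_YEAR
        vals = [0.02, 0.045, 0.07]
        stack = np.stack([np.full(tiny_grid.shape, v) for v in vals])
        series = make_series(tiny_grid, dates, {859: stack})
        slopes = fit_temporal_slope(series, min_valid_obs=2)
        # independent closed-form OLS oracle on the exact fractional-year grid
        expected = np.polyfit(t, vals, 1)[0]
        np.testing.assert_allclose(slopes.slope, expected, atol=1e-9)
        assert expected == pytest.approx(0.05, abs=5e-4)  # day-quantized time grid

    def test_exact_on_noiseless_line(self, tiny_grid):
        rng = np.random.default_rng(0)
        T = 50
        dates = daily_dates(T)
        t = np.array([(d - D0).days for d in dates]) / DAYS_PER_YEAR
        true_slope = rng.uniform(-0.1, 0.1, tiny_grid.shape)
        intercept = rng.uniform(0, 0.05, tiny_grid.shape)
        stack = intercept[None] + true_slope[None] * t[:, None, None]
        series = make_series(tiny_grid, dates, {859: stack})
        slopes = fit_temporal_slope(series, min_valid_obs=2)
        np.testing.assert_allclose(slopes.slope, true_slope, atol=1e-9)

    def test_unbiased_on_noisy_line(self):
        # >= 200 iid replicate pixels; mean within 2 standard errors of truth
        from reefwatch.grid import Grid

        grid = Grid(lat_min=10.0, lat_max=10.0449, lon_min=115.0, lon_max=115.0449)  # 20x20
        rng = np.random.default_rng(42)
        T = 40
        dates = daily_dates(T, start=D0)
        t = np.array([(d - D0).days for d in dates]) / DAYS_PER_YEAR
        true_slope = 0.05
        stack = 0.01 + true_slope * t[:, None, None] + rng.normal(0, 0.01, (T, *grid.shape))
        series = make_series(grid, dates, {859: stack})
        est = fit_temporal_slope(series, min_valid_obs=2).slope.ravel()
        assert est.size == 400
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - true_slope) < 2 * se + 1e-12

    def test_cloud_gaps_excluded_and_sentinel(self, tiny_grid):
        T = 12
        dates = daily_dates(T)
        stack = np.zeros((T, *tiny_grid.shape), dtype=np.float32)
        cloud = np.zeros((T, *tiny_grid.shape), dtype=bool)
        cloud[:, 0, 0] = True  # pixel (0,0) never observed
        cloud[2:, 0, 1] = True  # pixel (0,1): only 2 obs < min_valid_obs=10
        series = make_series(tiny_grid, dates, {859: stack}, cloud=cloud)
        slopes = fit_temporal_slope(series, min_valid_obs=10)
        assert np.isnan(slopes.slope[0, 0])
        assert np.isnan(slopes.slope[0, 1])
        assert slopes.n_obs[0, 0] == 0
        assert slopes.n_obs[0, 1] == 2
        assert np.isfinite(slopes.slope[1, 1])

    def test_cloudy_values_ignored(self, tiny_grid):
        # corrupting cloud-flagged values must not change the fit
        T = 30
        dates = daily_dates(T)
        t = np.array([(d - D0).days for d in dates]) / DAYS_PER_YEAR
        stack = (0.01 + 0.05 * t)[:, None, None] * np.ones(tiny_grid.shape)
        cloud = np.zeros((T, *tiny_grid.shape), dtype=bool)
        cloud[::3] = True
        corrupted = stack.copy()
        corrupted[cloud] = 99.0
        series = make_series(tiny_grid, dates, {859: corrupted}, cloud=cloud)
        slopes = fit_temporal_slope(series, min_valid_obs=2)
        np.testing.assert_allclose(slopes.slope, 0.05, atol=1e-9)


class TestDetectNewIslands:
    def slope_grid(self, tiny_grid, values, n_obs=100):
        from reefwatch.change_detection import SlopeGrid

        return SlopeGrid(
            slope=np.asarray(values, dtype=float),
            n_obs=np.full(np.asarray(values).shape, n_obs, dtype=int),
            min_valid_obs=10,
        )

    def test_all_below_threshold_empty(self, tiny_grid):
        sg = self.slope_grid(tiny_grid, np.full(tiny_grid.shape, 0.012))
        assert not detect_new_islands(sg).any()

    def test_above_threshold_flagged(self, tiny_grid):
        vals = np.full(tiny_grid.shape, 0.0)
        vals[2, 3] = 0.05
        sg = self.slope_grid(tiny_grid, vals)
        mask = detect_new_islands(sg)
        assert mask.sum() == 1 and mask[2, 3]

    def test_insufficient_obs_not_flagged(self, tiny_grid):
        sg = self.slope_grid(tiny_grid, np.full(tiny_grid.shape, 0.05), n_obs=5)
        assert not detect_new_islands(sg).any()

    def test_nan_slopes_never_flagged(self, tiny_grid):
        sg = self.slope_grid(tiny_grid, np.full(tiny_grid.shape, np.nan))
        assert not detect_new_islands(sg).any()

    def test_monotone_in_threshold(self, tiny_grid):
        rng = np.random.default_rng(7)
        sg = self.slope_grid(tiny_grid, rng.normal(0.013, 0.01, tiny_grid.shape))
        masks = [
            detect_new_islands(sg, DetectionConfig(slope_threshold=thr))
            for thr in (0.005, 0.013, 0.02, 0.05)
        ]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(hi <= lo)

    def test_water_to_island_transition_recovered(self, tiny_grid):
        # synthetic mid-series step from water (0.002) to land (0.25)
        T = 60
        dates = daily_dates(T)
        stack = np.full((T, *tiny_grid.shape), 0.002, dtype=np.float32)
        stack[T // 2 :, 3, 3] = 0.25
        series = make_series(tiny_grid, dates, {859: stack})
        slopes = fit_temporal_slope(series, min_valid_obs=10)
        mask = detect_new_islands(slopes)
        assert mask[3, 3]
        assert mask.sum() == 1


class TestIslandComponents:
    def test_empty_mask(self, tiny_grid):
        assert island_components(np.zeros(tiny_grid.shape, dtype=bool)) == []

    def test_12_pixel_component_area(self, tiny_grid):
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[1:4, 1:5] = True  # 12 pixels
        comps = island_components(mask)
        assert len(comps) == 1
        assert comps[0].n_pixels == 12
        assert comps[0].area_km2 == pytest.approx(0.75)

    def test_diagonal_pixels_are_one_component(self, tiny_grid):
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        comps = island_components(mask)
        assert len(comps) == 1
        assert comps[0].n_pixels == 2

    def test_separate_components_counted(self, tiny_grid):
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[0, 0] = True
        mask[5, 5] = True
        assert len(island_components(mask)) == 2

    def test_centroid_in_degrees_with_grid(self, small_grid):
        mask = small_grid.empty_mask()
        mask[4, 7] = True
        (c,) = island_components(mask, small_grid)
        lat, lon = small_grid.rowcol_to_latlon(4, 7)
        assert c.lat == pytest.approx(lat)
        assert c.lon == pytest.approx(lon)


class TestDetectionConfig:
    def test_thresholds_positive(self):
        with pytest.raises(ValueError):
            DetectionConfig(slope_threshold=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(shallow_threshold=-0.1)
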