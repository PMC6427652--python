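"""Humidity, heat index, daily aggregation and climatology statistics."""

import numpy as np
import pandas as pd
import pytest

from heatsignal.climate import (
    FieldSeries,
    GridDefinition,
    celsius_to_fahrenheit,
    compute_climatology,
    daily_aggregate,
    heat_index,
    heat_index_celsius,
    relative_humidity,
)


def magnus_rh_scalar(t, td):
    """Independent scalar evaluation of the saturation-ratio formula."""
    import math

    e = lambda x: math.exp(17.625 * x / (243.04 + x))
    return 100.0 * e(td) / e(t)


def hi_polynomial_scalar(t, r):
    """Independent scalar evaluation of the printed 9-term polynomial."""
    return (
        -42.38 + 2.05 * t + 10.14 * r - 0.22 * t * r - 6.84e-3 * t**2
        - 5.48e-2 * r**2 + 1.23e-3 * t**2 * r + 8.53e-4 * t * r**2
        - 1.99e-6 * t**2 * r**2
    )


class TestRelativeHumidity:
    def test_saturation_at_equal_temperatures(self):
        assert relative_humidity(25.0, 25.0) == pytest.approx(100.0)

    def test_scalar_oracle(self):
        # frozen from the independent scalar evaluation: 55.0775 %
        assert relative_humidity(30.0, 20.0) == pytest.approx(
            magnus_rh_scalar(30.0, 20.0), abs=1e-12
        )
        assert relative_humidity(30.0, 20.0) == pytest.approx(55.0775, abs=1e-3)

    def test_monotone_decreasing_in_air_temperature(self):
        assert relative_humidity(35.0, 20.0) < relative_humidity(30.0, 20.0)

    def test_saturation_iff_dewpoint_equals_air(self):
        rng = np.random.default_rng(42)
        t = rng.uniform(-40.0, 50.0, size=200)
        td = t - rng.uniform(0.01, 20.0, size=200)
        rh = relative_humidity(t, td)
        assert np.all(rh < 100.0)
        assert np.allclose(relative_humidity(t, t), 100.0)

    def test_supersaturation_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="dew point exceeds"):
            rh = relative_humidity(20.0, 21.0)
        assert rh == 100.0

    def test_denominator_validity(self):
        with pytest.raises(ValueError):
            relative_humidity(-250.0, -250.0)


class TestHeatIndex:
    def test_matches_independent_polynomial_on_random_pairs(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(60.0, 120.0, size=1000)
        r = rng.uniform(0.0, 100.0, size=1000)
        expected = np.array([hi_polynomial_scalar(ti, ri) for ti, ri in zip(t, r)])
        assert np.allclose(heat_index(t, r), expected, atol=1e-9)

    def test_strictly_increasing_in_temperature_over_hot_range(self):
        # verify the sign of dHI/dT numerically over 80..110 F at R=50
        t = np.linspace(80.0, 110.0, 301)
        hi = heat_index(t, 50.0)
        assert np.all(np.diff(hi) > 0)
        assert heat_index(95.0, 50.0) > heat_index(85.0, 50.0)

    def test_deterministic(self):
        a = heat_index(90.0, 50.0)
        b = heat_index(90.0, 50.0)
        assert a == b

    def test_celsius_wrapper_converts_first(self):
        t_c = 35.0
        assert heat_index_celsius(t_c, 40.0) == heat_index(
            celsius_to_fahrenheit(t_c), 40.0
        )
        assert celsius_to_fahrenheit(100.0) == 212.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            heat_index(np.nan, 50.0)


class TestDailyAggregate:
    def _subdaily(self, steps_per_day, days, values):
        grid = GridDefinition(lat=np.array([10.0]), lon=np.array([70.0]), resolution=0.75)
        times = pd.date_range("2010-01-01", periods=steps_per_day * days, freq=f"{24 // steps_per_day}h")
        return FieldSeries(grid, times, "T_mean", np.asarray(values, float)[:, None, None])

    def test_single_day_max_and_mean(self):
        fs = self._subdaily(4, 1, [20.0, 26.0, 31.0, 24.0])
        assert daily_aggregate(fs, "max").values[0, 0, 0] == 31.0
        assert daily_aggregate(fs, "mean").values[0, 0, 0] == 25.25

    def test_identity_on_daily_input(self):
        fs = self._subdaily(1, 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        out = daily_aggregate(fs, "mean")
        assert np.array_equal(out.values, fs.values)
        assert out.times.equals(fs.times.normalize())

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(3)
        fs = self._subdaily(4, 10, rng.normal(25.0, 5.0, size=40))
        mx = daily_aggregate(fs, "max").values
        mn = daily_aggregate(fs, "mean").values
        assert np.all(mx >= mn)

    def test_incomplete_day_dropped_or_strict_error(self):
        grid = GridDefinition(lat=np.array([10.0]), lon=np.array([70.0]), resolution=0.75)
        times = pd.DatetimeIndex(
            list(pd.date_range("2010-01-01", periods=4, freq="6h"))
            + [pd.Timestamp("2010-01-02 00:00")]
        )
        fs = FieldSeries(grid, times, "T_mean", np.arange(5.0)[:, None, None])
        with pytest.warns(UserWarning, match="incomplete"):
            out = daily_aggregate(fs, "mean")
        assert len(out.times) == 1
        with pytest.raises(ValueError, match="incomplete"):
            daily_aggregate(fs, "mean", strict=True)


class TestClimatology:
    def _daily(self, values):
        grid = GridDefinition(lat=np.array([10.0]), lon=np.array([70.0]), resolution=0.75)
        times = pd.date_range("2000-01-01", periods=len(values), freq="D")
        return FieldSeries(grid, times, "T_mean", np.asarray(values, float)[:, None, None])

    def test_order_statistic_interpolation(self):
        # 100 days valued 1..100: the 95th percentile interpolates to 95.05
        vals = np.arange(1.0, 101.0)
        n_pad = 366 - 100
        fs = self._daily(np.concatenate([vals, np.full(n_pad, 50.0)]))
        clim = compute_climatology(fs, (2000, 2000), levels=(0.95,))
        sample = fs.values[:, 0, 0]
        srt = np.sort(sample)
        rank = 0.95 * (len(srt) - 1)
        lo = int(np.floor(rank))
        oracle = srt[lo] + (rank - lo) * (srt[lo + 1] - srt[lo])
        assert clim.percentiles[0.95][0, 0] == pytest.approx(oracle, abs=1e-9)
        clim100 = np.percentile(vals, 95.0)
        assert clim100 == pytest.approx(95.05)

    def test_matches_sort_oracle_on_random_field(self):
        rng = np.random.default_rng(11)
        grid = GridDefinition(
            lat=np.array([10.0, 10.75]), lon=10.0 + 0.75 * np.arange(4), resolution=0.75
        )
        times = pd.date_range("2000-01-01", periods=400, freq="D")
        vals = rng.normal(25.0, 5.0, size=(400, 2, 4))
        fs = FieldSeries(grid, times, "T_mean", vals)
        clim = compute_climatology(fs, (2000, 2000), levels=(0.5, 0.95))
        in_period = vals[: 366]
        for lvl in (0.5, 0.95):
            for i in range(2):
                for j in range(4):
                    srt = np.sort(in_period[:, i, j])
                    rank = lvl * (len(srt) - 1)
                    lo = int(np.floor(rank))
                    hi = min(lo + 1, len(srt) - 1)
                    oracle = srt[lo] + (rank - lo) * (srt[hi] - srt[lo])
                    assert clim.percentiles[lvl][i, j] == pytest.approx(oracle, abs=1e-9)

    def test_constant_field(self):
        fs = self._daily(np.full(366, 7.5))
        clim = compute_climatology(fs, (2000, 2000), levels=(0.5, 0.95))
        assert clim.mean[0, 0] == 7.5
        assert clim.percentiles[0.5][0, 0] == 7.5
        assert clim.percentiles[0.95][0, 0] == 7.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=366)
        fs = self._daily(vals)
        clim = compute_climatology(fs, (2000, 2000), levels=(0.95,))
        perm = rng.permutation(vals)
        fs2 = self._daily(perm)
        clim2 = compute_climatology(fs2, (2000, 2000), levels=(0.95,))
        assert clim.percentiles[0.95][0, 0] == clim2.percentiles[0.95][0, 0]
        assert clim.mean[0, 0] == pytest.approx(clim2.mean[0, 0])

    def test_missing_coverage_reports_ranges(self):
        fs = self._daily(np.zeros(300))
        with pytest.raises(ValueError, match="missing"):
            compute_climatology(fs, (2000, 2000), levels=(0.95,))


class TestGridAndFieldValidation:
    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            GridDefinition(lat=np.array([0.0, 0.75, 1.6]), lon=np.array([0.0]),
                           resolution=0.75)

    def test_all_false_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            GridDefinition(lat=np.array([0.0]), lon=np.array([0.0]), resolution=0.75,
                           mask=np.array([[False]]))

    def test_nonmonotonic_times_rejected(self, grid2x2):
        times = pd.DatetimeIndex(["2010-01-02", "2010-01-01"])
        with pytest.raises(ValueError, match="increasing"):
            FieldSeries(grid2x2, times, "T_mean", np.zeros((2, 2, 2)))
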