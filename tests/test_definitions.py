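"""The four binary heat wave detectors and their region aggregation."""

import numpy as np
import pandas as pd
import pytest

from heatsignal.climate import ClimatologyStats, FieldSeries, GridDefinition
from heatsignal.definitions import (
    BinaryDaySeries,
    EhfParams,
    aggregate_any_pixel,
    detect_ehf,
    detect_imd,
    detect_threshold_duration,
    excess_heat_factor,
    filter_short_runs,
)


def make_clim(grid, mean_tmax=35.0, p95_tmean=30.0, p95_hi=100.0):
    shape = grid.shape
    return ClimatologyStats(
        grid=grid,
        reference_period=(1980, 2009),
        mean_tmax=np.full(shape, mean_tmax),
        p95_tmean=np.full(shape, p95_tmean),
        p95_hi=np.full(shape, p95_hi),
    )


def single_pixel_field(values, variable="T_max"):
    grid = GridDefinition(lat=np.array([20.0]), lon=np.array([78.0]), resolution=0.75)
    times = pd.date_range("2010-01-01", periods=len(values), freq="D")
    return FieldSeries(grid, times, variable, np.asarray(values, float)[:, None, None])


class TestImdRule:
    @pytest.mark.parametrize(
        "tm, tm_bar, expect",
        [
            (46.0, 30.0, True),   # absolute 45 degC branch
            (43.0, 38.0, False),  # 43 not > 38+5, strict inequality
            (44.5, 40.0, True),   # mean >= 40: +4 branch, 44.5 > 44
            (44.0, 40.0, False),  # boundary of the +4 branch, strict
            (45.0, 41.0, False),  # exactly 45 is not > 45; +4 branch needs > 45 too
            (45.1, 41.0, True),   # just over the absolute threshold
        ],
    )
    def test_branch_logic(self, tm, tm_bar, expect):
        fs = single_pixel_field([tm])
        mask = detect_imd(fs, make_clim(fs.grid, mean_tmax=tm_bar))
        assert bool(mask.flags[0, 0, 0]) is expect

    def test_no_duration_filter(self):
        fs = single_pixel_field([46.0, 20.0, 46.0])
        mask = detect_imd(fs, make_clim(fs.grid))
        assert list(mask.flags[:, 0, 0]) == [True, False, True]

    def test_grid_mismatch_rejected(self):
        fs = single_pixel_field([30.0])
        other = GridDefinition(lat=np.array([10.0, 10.75]), lon=np.array([70.0]),
                               resolution=0.75)
        with pytest.raises(ValueError, match="grid"):
            detect_imd(fs, make_clim(other))

    def test_monotone_under_warming(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(40.0, 4.0, size=60)
        fs = single_pixel_field(vals)
        clim = make_clim(fs.grid, mean_tmax=40.0)
        base = detect_imd(fs, clim).flags.copy()
        bumped = single_pixel_field(vals + rng.uniform(0, 3, size=60))
        warm = detect_imd(bumped, clim).flags
        assert np.all(warm[base])  # no flagged day becomes unflagged


class TestRunLengthFilter:
    def test_short_runs_removed(self):
        pattern = np.array([1, 1, 0, 1, 0], dtype=bool)[:, None]
        out = filter_short_runs(pattern, 2)
        assert list(out[:, 0]) == [True, True, False, False, False]

    def test_min_run_one_is_identity(self):
        rng = np.random.default_rng(1)
        pattern = rng.random((30, 3)) < 0.4
        assert np.array_equal(filter_short_runs(pattern, 1), pattern)

    @pytest.mark.parametrize("min_run", [2, 3])
    def test_matches_maximal_run_enumeration(self, min_run):
        rng = np.random.default_rng(123)
        for _ in range(200):
            pattern = rng.random(30) < 0.45
            got = filter_short_runs(pattern[:, None], min_run)[:, 0]
            # oracle: scan every maximal run explicitly
            expected = np.zeros(30, dtype=bool)
            i = 0
            while i < 30:
                if pattern[i]:
                    j = i
                    while j < 30 and pattern[j]:
                        j += 1
                    if j - i >= min_run:
                        expected[i:j] = True
                    i = j
                else:
                    i += 1
            assert np.array_equal(got, expected)

    def test_threshold_duration_detector(self):
        fs = single_pixel_field([31.0, 31.0, 20.0, 31.0, 20.0], variable="T_mean")
        mask = detect_threshold_duration(fs, np.array([[30.0]]), min_run=2)
        assert list(mask.flags[:, 0, 0]) == [True, True, False, False, False]


class TestExcessHeatFactor:
    def _series_with_history(self, tail_values, fill=20.0, n_history=32):
        vals = [fill] * n_history + list(tail_values)
        return single_pixel_field(vals, variable="T_mean")

    def test_direct_substitution(self):
        # three closing days at 30 degC after a 25 degC month, T95 = 28:
        # EHIsig = 2, EHIaccl = 5, EHF = 10
        fs = self._series_with_history([30.0, 30.0, 30.0], fill=25.0)
        clim = make_clim(fs.grid, p95_tmean=28.0)
        ehf = excess_heat_factor(fs, clim)
        assert ehf.values[-1, 0, 0] == pytest.approx(10.0)

    def test_acclimatisation_floor(self):
        # hot spell after an even hotter month: EHIaccl = -3 floors to 1
        fs = self._series_with_history([30.0, 30.0, 30.0], fill=33.0)
        clim = make_clim(fs.grid, p95_tmean=28.0)
        ehf = excess_heat_factor(fs, clim)
        assert ehf.values[-1, 0, 0] == pytest.approx(2.0)

    def test_zero_when_3day_mean_at_threshold(self):
        fs = self._series_with_history([28.0, 28.0, 28.0], fill=20.0)
        clim = make_clim(fs.grid, p95_tmean=28.0)
        ehf = excess_heat_factor(fs, clim)
        assert ehf.values[-1, 0, 0] == 0.0

    def test_zero_whenever_3day_mean_below_p95(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(27.0, 3.0, size=120)
        fs = single_pixel_field(vals, variable="T_mean")
        clim = make_clim(fs.grid, p95_tmean=30.0)
        ehf = excess_heat_factor(fs, clim).values[:, 0, 0]
        t3d = pd.Series(vals).rolling(3).mean().to_numpy()
        defined = ~np.isnan(ehf)
        # tiny margin: the oracle's rolling mean may differ in the last ulp
        assert np.all(ehf[defined & (t3d <= 30.0 - 1e-9)] == 0.0)

    def test_warmup_days_undefined_not_zero(self):
        fs = self._series_with_history([30.0] * 5, fill=25.0)
        clim = make_clim(fs.grid, p95_tmean=28.0)
        ehf = excess_heat_factor(fs, clim)
        warmup = EhfParams().warmup
        assert warmup == 32
        assert np.all(np.isnan(ehf.values[:warmup]))
        assert not np.any(np.isnan(ehf.values[warmup:]))

    def test_window_placement_is_non_overlapping(self):
        # 40 degC only on the scored 3 days: the 30-day window must not see it
        fs = self._series_with_history([40.0, 40.0, 40.0], fill=25.0)
        clim = make_clim(fs.grid, p95_tmean=28.0)
        ehf = excess_heat_factor(fs, clim)
        # EHIsig = 12, EHIaccl = 40 - 25 = 15 (not diluted by the spell itself)
        assert ehf.values[-1, 0, 0] == pytest.approx(12.0 * 15.0)

    def test_short_series_warns(self):
        fs = single_pixel_field([25.0] * 10, variable="T_mean")
        with pytest.warns(UserWarning, match="warm-up"):
            excess_heat_factor(fs, make_clim(fs.grid))


class TestDetectEhf:
    def test_strict_positivity(self):
        grid = GridDefinition(lat=np.array([20.0]), lon=np.array([78.0]), resolution=0.75)
        times = pd.date_range("2010-01-01", periods=3, freq="D")
        vals = np.array([0.0, 0.001, np.nan])[:, None, None]
        ehf = FieldSeries(grid, times, "EHF", vals)
        mask = detect_ehf(ehf)
        assert list(mask.flags[:, 0, 0]) == [False, True, False]
        assert list(mask.valid) == [True, True, False]

    def test_all_zero_field_gives_all_false(self):
        fs = single_pixel_field([0.0] * 4, variable="EHF")
        assert not detect_ehf(fs).flags.any()


class TestAggregateAnyPixel:
    def _mask(self, flags, valid=None):
        flags = np.asarray(flags, dtype=bool)
        grid = GridDefinition(
            lat=20.0 + 0.75 * np.arange(flags.shape[1]),
            lon=np.array([78.0]),
            resolution=0.75,
        )
        times = pd.date_range("2010-01-01", periods=flags.shape[0], freq="D")
        from heatsignal.definitions import HeatwaveMask

        return HeatwaveMask(grid, times, "T95", flags[:, :, None], valid=valid)

    def test_single_flagged_pixel_flags_the_day(self):
        mask = self._mask([[True, False, False], [False, False, False]])
        series = aggregate_any_pixel(mask)
        assert list(series.flags) == [True, False]

    def test_single_pixel_grid_is_identity(self):
        mask = self._mask([[True], [False], [True]])
        assert list(aggregate_any_pixel(mask).flags) == [True, False, True]

    def test_invalid_days_excluded(self):
        mask = self._mask(
            [[True], [True], [False]], valid=np.array([False, True, True])
        )
        series = aggregate_any_pixel(mask)
        assert len(series.times) == 2
        assert list(series.flags) == [True, False]

    def test_region_day_count_dominates_any_pixel(self):
        rng = np.random.default_rng(9)
        flags = rng.random((50, 4)) < 0.3
        series = aggregate_any_pixel(self._mask(flags))
        for j in range(4):
            assert series.flags.sum() >= flags[:, j].sum()


class TestMonotonicityUnderWarming:
    def test_t95_flags_never_lost_when_warming(self):
        rng = np.random.default_rng(31)
        vals = rng.normal(29.0, 2.0, size=80)
        fs = single_pixel_field(vals, variable="T_mean")
        thr = np.array([[30.0]])
        base = detect_threshold_duration(fs, thr, 2).flags.copy()
        warm = detect_threshold_duration(
            single_pixel_field(vals + rng.uniform(0, 2, size=80), variable="T_mean"),
            thr,
            2,
        ).flags
        assert np.all(warm[base])

    def test_ehf_flags_never_lost_when_warming(self):
        rng = np.random.default_rng(32)
        vals = rng.normal(28.0, 2.5, size=120)
        fs = single_pixel_field(vals, variable="T_mean")
        clim = make_clim(fs.grid, p95_tmean=29.0)
        base = detect_ehf(excess_heat_factor(fs, clim)).flags.copy()
        bump = np.zeros(120)
        bump[rng.integers(0, 120, size=20)] = rng.uniform(0, 3, size=20)
        warm = detect_ehf(
            excess_heat_factor(
                single_pixel_field(vals + bump, variable="T_mean"), clim
            )
        ).flags
        assert np.all(warm[base])
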