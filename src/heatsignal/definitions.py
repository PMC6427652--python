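"""Binary heat wave detectors on daily gridded fields.

Four detectors are implemented, each returning a per-pixel boolean
:class:`HeatwaveMask` which can be collapsed to a region-level daily
series with :func:`aggregate_any_pixel` (a day counts as a heat wave
day if *any* masked-in pixel is flagged):

``IMD``
    The India Meteorological Department rule: flag a day when the daily
    maximum temperature TM satisfies ``TM > 45`` degC, or exceeds its
    30-year mean by 4 degC where that mean is at least 40 degC, or by
    5 degC where the mean is below 40 degC.  No minimum duration.
``T95``
    Daily mean temperature above its pooled 95th percentile for at
    least two consecutive days.
``HI95``
    Mean daily heat index above its pooled 95th percentile for at least
    two consecutive days.
``EHF``
    Excess heat factor positive.  EHF combines a significance index
    (3-day mean temperature minus the 95th percentile) with an
    acclimatisation factor (3-day mean minus the preceding 30-day
    mean, floored at 1).

All exceedance comparisons are strict (``>``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimatologyStats, FieldSeries, GridDefinition

__all__ = [
    "HeatwaveMask",
    "BinaryDaySeries",
    "EhfParams",
    "detect_imd",
    "detect_threshold_duration",
    "detect_t95",
    "detect_hi95",
    "excess_heat_factor",
    "detect_ehf",
    "aggregate_any_pixel",
    "filter_short_runs",
]


@dataclass(eq=False)
class HeatwaveMask:
    """Per-pixel daily heat wave flags for one definition.

    ``valid`` marks days on which the detector is defined at all; the
    EHF warm-up window is invalid (excluded), not merely unflagged.
    """

    grid: GridDefinition
    times: pd.DatetimeIndex
    definition: str
    flags: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.flags = np.asarray(self.flags, dtype=bool)
        expected = (len(self.times),) + self.grid.shape
        if self.flags.shape != expected:
            raise ValueError(f"flags shape {self.flags.shape} != {expected}")
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (len(self.times),):
            raise ValueError("valid must be one boolean per day")
        # flags may only sit on masked-in pixels and valid days
        self.flags &= self.grid.mask[None, :, :]
        self.flags[~self.valid] = False


@dataclass(eq=False)
class BinaryDaySeries:
    """A daily 0/1 heat wave occurrence series for a region."""

    times: pd.DatetimeIndex
    flags: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.times) == 0:
            raise ValueError("series must cover at least one day")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ValueError("times must be strictly increasing, no duplicates")
        if self.flags.shape != (len(self.times),):
            raise ValueError("flags must be one boolean per day")

    def as_series(self) -> pd.Series:
        return pd.Series(self.flags, index=self.times, name=self.source)


@dataclass(frozen=True)
class EhfParams:
    """Window layout for the excess heat factor.

    The significance window is the trailing ``sig_window`` days ending
    on the scored day; the acclimatisation window is the
    ``accl_window`` days immediately before it (non-overlapping).
    """

    sig_window: int = 3
    accl_window: int = 30

    def __post_init__(self) -> None:
        if self.sig_window < 1 or self.accl_window < 1:
            raise ValueError("EHF windows must be at least one day")

    @property
    def warmup(self) -> int:
        """Days at the start of the series on which EHF is undefined."""
        return self.accl_window + self.sig_window - 1


def detect_imd(tmax_daily: FieldSeries, clim: ClimatologyStats) -> HeatwaveMask:
    """IMD heat wave rule on daily maximum temperature.

    Flag = (TM > 45) or (TM > mean+4 and mean >= 40) or
    (TM > mean+5 and mean < 40), with the climatological mean of TM
    taken over the reference period.  The boundary case mean == 40
    falls in the +4 branch (the more conservative detection).
    """
    tmax_daily.grid.require_same(clim.grid)
    tm = tmax_daily.values
    tm_bar = clim.mean_tmax[None, :, :]
    flags = (
        (tm > 45.0)
        | ((tm > tm_bar + 4.0) & (tm_bar >= 40.0))
        | ((tm > tm_bar + 5.0) & (tm_bar < 40.0))
    )
    return HeatwaveMask(tmax_daily.grid, tmax_daily.times, "IMD", flags)


def filter_short_runs(exceed: np.ndarray, min_run: int) -> np.ndarray:
    """Zero out True-runs shorter than ``min_run`` along the first axis."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    exceed = np.asarray(exceed, dtype=bool)
    if min_run == 1:
        return exceed.copy()
    flat = exceed.reshape(exceed.shape[0], -1)
    out = np.zeros_like(flat)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        # run boundaries via padded diff
        padded = np.concatenate(([False], col, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                out[s:e, j] = True
    return out.reshape(exceed.shape)


def detect_threshold_duration(
    daily: FieldSeries,
    threshold: np.ndarray,
    min_run: int,
    *,
    definition: str = "threshold",
) -> HeatwaveMask:
    """Flag per-pixel days strictly above a threshold, sustained >= min_run days.

    Exceedance runs shorter than ``min_run`` are removed pixel by pixel.
    """
    threshold = np.asarray(threshold, dtype=float)
    if threshold.shape != daily.grid.shape:
        raise ValueError("threshold shape does not match grid")
    exceed = daily.values > threshold[None, :, :]
    flags = filter_short_runs(exceed, min_run)
    valid = ~np.all(np.isnan(daily.values), axis=(1, 2))
    return HeatwaveMask(daily.grid, daily.times, definition, flags, valid=valid)


def detect_t95(tmean_daily: FieldSeries, clim: ClimatologyStats, min_run: int = 2) -> HeatwaveMask:
    """Daily mean temperature above its pooled p95 for >= 2 days."""
    tmean_daily.grid.require_same(clim.grid)
    return detect_threshold_duration(tmean_daily, clim.p95_tmean, min_run, definition="T95")


def detect_hi95(hi_daily: FieldSeries, clim: ClimatologyStats, min_run: int = 2) -> HeatwaveMask:
    """Mean daily heat index above its pooled p95 for >= 2 days."""
    hi_daily.grid.require_same(clim.grid)
    return detect_threshold_duration(hi_daily, clim.p95_hi, min_run, definition="HI95")


def _trailing_mean(values: np.ndarray, window: int, lag: int) -> np.ndarray:
    """Mean of days ``i-lag-window+1 .. i-lag`` per day ``i`` (NaN when undefined)."""
    n = values.shape[0]
    csum = np.concatenate(
        [np.zeros((1,) + values.shape[1:]), np.cumsum(values, axis=0)], axis=0
    )
    out = np.full_like(values, np.nan, dtype=float)
    first = window + lag - 1
    idx = np.arange(first, n)
    out[idx] = (csum[idx - lag + 1] - csum[idx - lag - window + 1]) / window
    return out


def excess_heat_factor(
    tmean_daily: FieldSeries,
    clim: ClimatologyStats,
    params: EhfParams = EhfParams(),
) -> FieldSeries:
    """Excess heat factor per pixel and day.

    ``EHF = max(0, T3d - T95) * max(1, T3d - T30d)`` where T3d is the
    trailing 3-day mean ending on the scored day and T30d the mean of
    the 30 days immediately preceding that window.  The first
    ``accl_window + sig_window - 1`` days are undefined (NaN), not zero.
    """
    tmean_daily.grid.require_same(clim.grid)
    n = tmean_daily.n_times
    if n <= params.warmup:
        warnings.warn(
            f"series of {n} days is shorter than the EHF warm-up of "
            f"{params.warmup} days; all days undefined",
            stacklevel=2,
        )
    t_sig = _trailing_mean(tmean_daily.values, params.sig_window, lag=0)
    t_accl = _trailing_mean(tmean_daily.values, params.accl_window, lag=params.sig_window)
    ehi_sig = t_sig - clim.p95_tmean[None, :, :]
    ehi_accl = t_sig - t_accl
    ehf = np.maximum(0.0, ehi_sig) * np.maximum(1.0, ehi_accl)
    ehf[: params.warmup] = np.nan
    return FieldSeries(tmean_daily.grid, tmean_daily.times, "EHF", ehf)


def detect_ehf(ehf: FieldSeries) -> HeatwaveMask:
    """Flag days of strictly positive excess heat factor.

    Undefined (NaN) days are marked invalid and never flagged.
    """
    with np.errstate(invalid="ignore"):
        flags = ehf.values > 0.0
    valid = ~np.all(np.isnan(ehf.values), axis=(1, 2))
    return HeatwaveMask(ehf.grid, ehf.times, "EHF", flags, valid=valid)


def aggregate_any_pixel(mask: HeatwaveMask) -> BinaryDaySeries:
    """Region series: a day is a heat wave day if any masked-in pixel is flagged.

    Invalid days (detector undefined) are dropped from the output.
    """
    if not mask.grid.mask.any():
        raise ValueError("empty region mask")
    any_flag = mask.flags[:, mask.grid.mask].any(axis=1)
    keep = mask.valid
    return BinaryDaySeries(mask.times[keep], any_flag[keep], source=mask.definition)
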