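"""The social-media heat wave signal.

Turns a keyword-filtered tweet archive into a daily count series,
normalises it by the (linearly interpolated) number of active platform
users, and binarises the raw daily counts with a small threshold —
by default two tweets per day declare a heat wave day.

Normalisation is expressed as tweets per million users.  For periods
coarser than a day the default is period-total counts divided by the
period-mean user count; summing the daily normalised values instead is
available via ``mode="daily_sum"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .definitions import BinaryDaySeries

__all__ = [
    "TweetCountSeries",
    "ActiveUserSeries",
    "NormalizedSeries",
    "count_daily",
    "interpolate_users",
    "normalize_per_million",
    "binarize",
    "read_tweet_archive",
    "read_user_series",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class TweetCountSeries:
    """Daily tweet counts over a contiguous date range (missing days are 0)."""

    dates: pd.DatetimeIndex
    counts: np.ndarray
    query_label: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(rounded, self.counts):
                raise ValueError("tweet counts must be integers")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("tweet counts must be non-negative")
        if len(self.dates) == 0:
            raise ValueError("empty date range")
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if not self.dates.equals(full):
            raise ValueError("dates must be contiguous daily (zero-fill gaps)")
        if self.counts.shape != (len(self.dates),):
            raise ValueError("one count per date required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.dates, name="tweets")


@dataclass(eq=False)
class ActiveUserSeries:
    """Quarterly active-user totals used as the normaliser."""

    quarter_dates: pd.DatetimeIndex
    users: np.ndarray

    def __post_init__(self) -> None:
        self.quarter_dates = pd.DatetimeIndex(self.quarter_dates)
        self.users = np.asarray(self.users, dtype=float)
        if len(self.quarter_dates) < 1:
            raise ValueError("need at least one quarter")
        if not self.quarter_dates.is_monotonic_increasing or self.quarter_dates.has_duplicates:
            raise ValueError("quarter dates must be strictly increasing")
        if self.users.shape != (len(self.quarter_dates),):
            raise ValueError("one user count per quarter required")
        if np.any(self.users <= 0):
            raise ValueError("user counts must be positive")


@dataclass(eq=False)
class NormalizedSeries:
    """Tweets per million users at daily, monthly or annual resolution."""

    period_starts: pd.DatetimeIndex
    values: np.ndarray
    period: str

    def __post_init__(self) -> None:
        self.period_starts = pd.DatetimeIndex(self.period_starts)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("normalised values must be finite and >= 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.period_starts, name="tweets_per_million")


def count_daily(
    archive: Iterable[tuple] | pd.DataFrame,
    date_range: tuple[str, str],
    *,
    substring: str | None = None,
    query_label: str = "",
) -> TweetCountSeries:
    """Count archive rows per calendar day over a fixed date range.

    ``archive`` is an iterable of (timestamp, text) rows or a DataFrame
    with ``timestamp`` and ``text`` columns; the archive is assumed to
    be already query-filtered, but an optional case-insensitive
    ``substring`` re-filter is applied if given.  Unparseable
    timestamps are skipped and logged; days with no rows count zero.
    """
    if isinstance(archive, pd.DataFrame):
        rows = list(zip(archive["timestamp"], archive.get("text", [""] * len(archive))))
    else:
        rows = list(archive)
    full = pd.date_range(date_range[0], date_range[1], freq="D")
    if not rows:
        warnings.warn("empty tweet archive: producing an all-zero series", stacklevel=2)
        return TweetCountSeries(full, np.zeros(len(full), dtype=np.int64), query_label)
    stamps = pd.to_datetime([r[0] for r in rows], errors="coerce", format="mixed")
    bad = stamps.isna()
    if bad.any():
        logger.warning("skipping %d rows with unparseable timestamps", int(bad.sum()))
    keep = ~np.asarray(bad)
    if substring is not None:
        texts = np.array([str(r[1]).lower() for r in rows])
        keep &= np.char.find(texts, substring.lower()) >= 0
    days = stamps[keep].normalize()
    counts = (
        pd.Series(1, index=days).groupby(level=0).sum().reindex(full, fill_value=0)
    )
    return TweetCountSeries(full, counts.to_numpy(dtype=np.int64), query_label)


def interpolate_users(quarterly: ActiveUserSeries, dates) -> np.ndarray:
    """Piecewise-linear daily user counts from the quarterly series.

    Dates outside the covered range take the boundary value, with a
    warning (constant extrapolation).
    """
    dates = pd.DatetimeIndex(dates)
    knots = quarterly.quarter_dates.asi8.astype(float)
    query = dates.asi8.astype(float)
    if np.any(query < knots[0]) or np.any(query > knots[-1]):
        warnings.warn(
            "dates outside the user series range: extrapolating with the "
            "boundary value",
            stacklevel=2,
        )
    return np.interp(query, knots, quarterly.users)


def normalize_per_million(
    counts: TweetCountSeries,
    users: ActiveUserSeries,
    period: str = "year",
    *,
    mode: str = "period_mean",
) -> NormalizedSeries:
    """Tweet counts per million active users per period.

    ``period`` is ``"day"``, ``"month"`` or ``"year"``.  With the
    default ``mode="period_mean"`` the value is the period-total count
    divided by the period-mean interpolated user count (in millions);
    ``mode="daily_sum"`` sums the per-day normalised values instead.
    """
    freq = {"day": "D", "month": "MS", "year": "YS"}.get(period)
    if freq is None:
        raise ValueError(f"unknown period {period!r}")
    if mode not in ("period_mean", "daily_sum"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    daily_users = interpolate_users(users, counts.dates)
    if np.any(daily_users <= 0):
        raise ValueError("interpolated user counts must be positive")
    s = counts.as_series()
    u = pd.Series(daily_users, index=counts.dates)
    if mode == "period_mean":
        totals = s.resample(freq).sum()
        mean_users = u.resample(freq).mean()
        vals = totals / (mean_users / 1e6)
    else:
        vals = (s / (u / 1e6)).resample(freq).sum()
    return NormalizedSeries(vals.index, vals.to_numpy(), period)


def binarize(counts: TweetCountSeries, threshold: int = 2) -> BinaryDaySeries:
    """Declare a heat wave day when the raw daily count reaches ``threshold``.

    Applied to raw counts, not normalised values.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return BinaryDaySeries(counts.dates, counts.counts >= threshold, source="twitter")


def read_tweet_archive(path: str | Path) -> pd.DataFrame:
    """Read a tweet archive CSV with columns ``timestamp`` and ``text``."""
    df = pd.read_csv(path, dtype=str)
    if "timestamp" not in df.columns:
        raise ValueError("tweet archive needs a 'timestamp' column")
    if "text" not in df.columns:
        df["text"] = ""
    return df[["timestamp", "text"]]


def read_user_series(path: str | Path) -> ActiveUserSeries:
    """Read an active-user CSV with columns ``quarter_start`` and ``users``."""
    df = pd.read_csv(path)
    return ActiveUserSeries(
        pd.DatetimeIndex(pd.to_datetime(df["quarter_start"])),
        df["users"].to_numpy(dtype=float),
    )
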