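"""Verification and impact evaluation.

Two strands:

* **Binary verification** of a candidate heat wave day series (a
  climate-based definition) against a reference series (the social
  signal), via the 2x2 contingency table and five skill scores:
  percentage correct, hit rate, miss rate, false alarm rate and
  frequency bias.
* **Impact correlation** of yearly/monthly indicator series against
  heat-related mortality tables (Pearson and Spearman, reported with
  significance ``1 - p``).

Contingency convention
----------------------
``a`` = days flagged by both series, ``b`` = candidate-only,
``c`` = reference-only, ``d`` = neither.  With the social signal as the
reference this makes the hit rate ``a/(a+c)`` the fraction of
reference heat wave days the candidate captures, the false alarm rate
``b/(b+d)`` the fraction of reference non-days it falsely flags, and
the bias ``(a+b)/(a+c)`` the candidate/reference event-day ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .definitions import BinaryDaySeries

__all__ = [
    "MortalityTable",
    "ContingencyTable",
    "SkillScoreSet",
    "CorrelationResult",
    "contingency",
    "skill_scores",
    "heatwave_day_fraction",
    "correlate",
    "aggregate_mortality",
    "top_regions",
    "load_imd_state_mortality",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class MortalityTable:
    """Heat-related excess deaths per period, region and source.

    ``rows`` has columns ``period`` (a year as ``"2015"`` or a month as
    ``"2015-05"``), ``region``, ``source`` and ``deaths``; the triple
    (period, region, source) is unique and deaths are non-negative
    integers.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"period", "region", "source", "deaths"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"mortality table missing columns {sorted(missing)}")
        df = self.rows.copy()
        df["period"] = df["period"].astype(str)
        df["deaths"] = df["deaths"].astype(int)
        if (df["deaths"] < 0).any():
            raise ValueError("deaths must be non-negative")
        if df.duplicated(["period", "region", "source"]).any():
            raise ValueError("(period, region, source) must be unique")
        self.rows = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return cls(pd.read_csv(path))

    @property
    def sources(self) -> list[str]:
        return sorted(self.rows["source"].unique())


def load_imd_state_mortality() -> MortalityTable:
    """Annual heat-related deaths per Indian state, 2010-2015.

    As tabulated in the India Meteorological Department annual weather
    report summaries (source label ``IMD``).
    """
    ref = resources.files("heatsignal.data").joinpath("imd_state_mortality.csv")
    with resources.as_file(ref) as path:
        return MortalityTable.from_csv(path)


@dataclass(frozen=True)
class ContingencyTable:
    """Joint day counts of a reference and a candidate binary series."""

    a: int  # flagged by both
    b: int  # candidate only
    c: int  # reference only
    d: int  # neither
    reference_label: str = "reference"
    candidate_label: str = "candidate"

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SkillScoreSet:
    """The five binary verification scores; None marks an undefined score."""

    percentage_correct: float | None
    hit_rate: float | None
    miss_rate: float | None
    false_alarm_rate: float | None
    bias: float | None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {
            "percentage_correct": self.percentage_correct,
            "hit_rate": self.hit_rate,
            "miss_rate": self.miss_rate,
            "false_alarm_rate": self.false_alarm_rate,
            "bias": self.bias,
        }


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    significance: float  # 1 - p
    n: int
    method: str
    defined: bool = True


def contingency(reference: BinaryDaySeries, candidate: BinaryDaySeries) -> ContingencyTable:
    """2x2 contingency table of two daily binary series.

    Series covering different date ranges are intersected with a
    warning; an empty overlap is an error.
    """
    r = reference.as_series()
    c = candidate.as_series()
    common = r.index.intersection(c.index)
    if len(common) == 0:
        raise ValueError("binary series have no overlapping days")
    if len(common) != len(r) or len(common) != len(c):
        logger.warning(
            "date ranges differ; comparing the %d-day intersection", len(common)
        )
    rf = r.loc[common].to_numpy(dtype=bool)
    cf = c.loc[common].to_numpy(dtype=bool)
    return ContingencyTable(
        a=int(np.sum(rf & cf)),
        b=int(np.sum(~rf & cf)),
        c=int(np.sum(rf & ~cf)),
        d=int(np.sum(~rf & ~cf)),
        reference_label=reference.source,
        candidate_label=candidate.source,
    )


def skill_scores(ct: ContingencyTable) -> SkillScoreSet:
    """Five binary skill scores from a contingency table.

    PC = (a+d)/n, HR = a/(a+c), MR = c/(a+c), FAR = b/(b+d),
    Bias = (a+b)/(a+c).  Scores with a zero denominator are reported
    as undefined rather than NaN.
    """
    if ct.n == 0:
        raise ValueError("empty contingency table")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    pc = ct.a + ct.d
    scores = SkillScoreSet(
        percentage_correct=pc / ct.n,
        hit_rate=ratio(ct.a, ct.a + ct.c, "hit_rate"),
        miss_rate=ratio(ct.c, ct.a + ct.c, "miss_rate"),
        false_alarm_rate=ratio(ct.b, ct.b + ct.d, "false_alarm_rate"),
        bias=ratio(ct.a + ct.b, ct.a + ct.c, "bias"),
        undefined=tuple(undefined),
    )
    return scores


def heatwave_day_fraction(series: BinaryDaySeries) -> float:
    """Fraction of days flagged as heat wave days."""
    return float(series.flags.sum()) / len(series.flags)


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with significance ``1 - p``.

    The p-value is the two-sided t-approximation with n-2 degrees of
    freedom (Spearman uses average ranks for ties).  Zero variance in
    either input yields an undefined result (``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, method, defined=False)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(r), float(1.0 - p), n, method)


def aggregate_mortality(
    table: MortalityTable,
    region: str | None = None,
    years: tuple[int, int] | None = None,
    source: str | None = None,
) -> int:
    """Total deaths over a (region, year-range, source) selection."""
    df = table.rows
    if region is not None:
        df = df[df["region"] == region]
    if source is not None:
        df = df[df["source"] == source]
    if years is not None:
        period_year = df["period"].str.slice(0, 4).astype(int)
        df = df[(period_year >= years[0]) & (period_year <= years[1])]
    if df.empty:
        raise ValueError("mortality selection matched no rows")
    return int(df["deaths"].sum())


def top_regions(
    table: MortalityTable,
    k: int = 2,
    years: tuple[int, int] | None = None,
    source: str | None = None,
) -> list[tuple[str, int]]:
    """The k regions with the highest total deaths over the selection."""
    df = table.rows
    if source is not None:
        df = df[df["source"] == source]
    if years is not None:
        period_year = df["period"].str.slice(0, 4).astype(int)
        df = df[(period_year >= years[0]) & (period_year <= years[1])]
    totals = df.groupby("region")["deaths"].sum().sort_values(ascending=False)
    return [(str(r), int(v)) for r, v in totals.head(k).items()]
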