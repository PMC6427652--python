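"""End-to-end orchestration: from raw inputs to the result tables.

:func:`run_full` executes the four analysis stages — build the social
signal, correlate indicators and tweets with mortality, detect heat
waves under each climate-based definition, and verify the detectors
against the social reference — and writes four CSV tables plus a run
log of every resolved configuration choice:

* ``indicators.csv`` — the nine yearly climatic indicators;
* ``correlations.csv`` — Pearson/Spearman coefficients (with
  significance ``1 - p``) of each indicator and the normalised tweet
  series against each mortality source;
* ``skill_scores.csv`` — the five binary skill scores of each
  definition against the tweet-based reference;
* ``day_fractions.csv`` — heat wave day fraction per series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as cl
from . import definitions as hw
from . import evaluation as ev
from . import indicators as ind
from . import social as soc
from .synthetic import SyntheticConfig, SyntheticWorld, generate_world

__all__ = ["RunConfig", "RunResult", "run_full", "build_fields", "detect_all"]

logger = logging.getLogger(__name__)

ALL_DEFINITIONS = ("IMD", "T95", "HI95", "EHF")


@dataclass
class RunConfig:
    """Everything a full run needs; exactly one of synthetic/real inputs."""

    synthetic: SyntheticConfig | None = None
    climate_netcdf: str | None = None
    climate_variables: dict | None = None  # file var -> {T_mean,T_max,T_dew}
    population_csv: str | None = None
    tweets_csv: str | None = None
    users_csv: str | None = None
    mortality_csv: str | None = None
    reference_period: tuple[int, int] = (1980, 2009)
    study_period: tuple[int, int] = (2010, 2017)
    definitions: tuple[str, ...] = ALL_DEFINITIONS
    tweet_threshold: int = 2
    normalization: str = "period_mean"
    pop_scaling: str = "sum"
    outdir: str = "results"

    def __post_init__(self) -> None:
        real = self.climate_netcdf is not None
        if real == (self.synthetic is not None):
            raise ValueError("specify exactly one of synthetic config or input paths")
        unknown = set(self.definitions) - set(ALL_DEFINITIONS)
        if unknown:
            raise ValueError(f"unknown definitions {sorted(unknown)}")
        if self.reference_period[1] >= self.study_period[0]:
            raise ValueError("reference and study periods must not overlap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        for key in ("reference_period", "study_period"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "definitions" in raw:
            raw["definitions"] = tuple(raw["definitions"])
        return cls(**raw)

    def resolved_settings(self) -> dict:
        """Every paper-gap decision as an explicit, loggable key."""
        return {
            "percentile_method": "linear interpolation between order statistics",
            "daily_max_rule": "max of sub-daily steps",
            "rh_clamp": "[0, 100]; supersaturation treated as 100%",
            "imd_tie_at_mean_40C": "+4 degC branch",
            "ehf_windows": "trailing 3-day; 30-day immediately preceding",
            "ehf_warmup": "undefined (excluded), not zero",
            "contingency_convention": "b = candidate-only, c = reference-only",
            "correlation_p": "two-sided t-approximation, n-2 df",
            "tweet_threshold": self.tweet_threshold,
            "normalization": self.normalization,
            "pop_scaling": self.pop_scaling,
            "reference_period": list(self.reference_period),
            "study_period": list(self.study_period),
            "definitions": list(self.definitions),
        }


@dataclass(eq=False)
class RunResult:
    indicators: pd.DataFrame
    correlations: pd.DataFrame
    skill: pd.DataFrame
    day_fractions: pd.DataFrame
    binary_series: dict
    world: SyntheticWorld | None = None


def build_fields(
    tmean: cl.FieldSeries, tmax: cl.FieldSeries, tdew: cl.FieldSeries
) -> tuple[cl.FieldSeries, cl.FieldSeries]:
    """Derive relative humidity and heat index fields from daily T and Td."""
    rh = cl.relative_humidity(tmean.values, tdew.values)
    hi = cl.heat_index_celsius(tmean.values, rh)
    return (
        cl.FieldSeries(tmean.grid, tmean.times, "RH", rh),
        cl.FieldSeries(tmean.grid, tmean.times, "HI", hi),
    )


def detect_all(
    tmean: cl.FieldSeries,
    tmax: cl.FieldSeries,
    hi: cl.FieldSeries,
    clim: cl.ClimatologyStats,
    study_years: list[int],
    definitions: tuple[str, ...] = ALL_DEFINITIONS,
) -> tuple[dict[str, hw.BinaryDaySeries], cl.FieldSeries]:
    """Run the selected detectors; return region-level binary series and the EHF field.

    The excess heat factor is computed on the full series (so the study
    years have a complete warm-up history) and then restricted to the
    study years, as are the other detectors.
    """
    ehf_full = hw.excess_heat_factor(tmean, clim)
    ehf_study = ehf_full.select_years(study_years)
    out: dict[str, hw.BinaryDaySeries] = {}
    for name in definitions:
        if name == "IMD":
            mask = hw.detect_imd(tmax.select_years(study_years), clim)
        elif name == "T95":
            mask = hw.detect_t95(tmean.select_years(study_years), clim)
        elif name == "HI95":
            mask = hw.detect_hi95(hi.select_years(study_years), clim)
        elif name == "EHF":
            mask = hw.detect_ehf(ehf_study)
        else:  # pragma: no cover - guarded by RunConfig
            raise ValueError(name)
        out[name] = hw.aggregate_any_pixel(mask)
    return out, ehf_study


def _annual_deaths(mort: ev.MortalityTable, source: str) -> pd.Series:
    df = mort.rows
    sel = df[(df["source"] == source) & (df["period"].str.len() == 4)]
    return pd.Series(
        sel["deaths"].to_numpy(dtype=float),
        index=sel["period"].astype(int).to_numpy(),
    ).groupby(level=0).sum()


def _correlation_rows(
    annual_signals: pd.DataFrame, mort: ev.MortalityTable
) -> pd.DataFrame:
    rows = []
    for source in mort.sources:
        deaths = _annual_deaths(mort, source)
        joined = annual_signals.join(deaths.rename("deaths"), how="inner").dropna()
        dropped = len(annual_signals) - len(joined)
        if dropped:
            logger.warning("dropping %d unmatched year(s) for source %s", dropped, source)
        for col in annual_signals.columns:
            for method in ("pearson", "spearman"):
                if len(joined) < 3:
                    res = ev.CorrelationResult(np.nan, np.nan, len(joined), method, defined=False)
                else:
                    res = ev.correlate(joined[col].to_numpy(), joined["deaths"].to_numpy(), method)
                rows.append(
                    {
                        "source": source,
                        "signal": col,
                        "method": method,
                        "coefficient": res.coefficient,
                        "significance": res.significance,
                        "n": res.n,
                        "defined": res.defined,
                    }
                )
    return pd.DataFrame(rows)


def run_full(cfg: RunConfig) -> RunResult:
    """Execute the whole pipeline and write the result tables as CSV."""
    stage = "inputs"
    try:
        if cfg.synthetic is not None:
            world = generate_world(cfg.synthetic)
            tmean, tmax, tdew = world.climate.tmean, world.climate.tmax, world.climate.tdew
            pop = world.population
            tweets, users = world.tweets, world.users
            mortality = world.mortality
            reference_period = cfg.synthetic.reference_period
            study_period = cfg.synthetic.study_period
        else:
            world = None
            fields = cl.read_fields_netcdf(cfg.climate_netcdf, cfg.climate_variables)
            tmean, tmax, tdew = fields["T_mean"], fields["T_max"], fields["T_dew"]
            if len(tmean.times.normalize().unique()) != len(tmean.times):
                tmean = cl.daily_aggregate(tmean, "mean")
                tmax = cl.daily_aggregate(tmax, "max")
                tdew = cl.daily_aggregate(tdew, "mean")
            pop_df = pd.read_csv(cfg.population_csv)
            persons = np.zeros(tmean.grid.shape)
            for _, row in pop_df.iterrows():
                i = int(np.abs(tmean.grid.lat - row["lat"]).argmin())
                j = int(np.abs(tmean.grid.lon - row["lon"]).argmin())
                persons[i, j] += float(row["persons"])
            pop = ind.PopulationGrid(tmean.grid, persons)
            archive = soc.read_tweet_archive(cfg.tweets_csv)
            study_period = cfg.study_period
            tweets = soc.count_daily(
                archive,
                (f"{study_period[0]}-01-01", f"{study_period[1]}-12-31"),
            )
            users = soc.read_user_series(cfg.users_csv)
            mortality = ev.MortalityTable.from_csv(cfg.mortality_csv)
            reference_period = cfg.reference_period

        study_years = list(range(study_period[0], study_period[1] + 1))

        stage = "derived fields"
        _, hi = build_fields(tmean, tmax, tdew)

        stage = "climatology"
        clim = cl.build_climatology_stats(tmax, tmean, hi, reference_period)

        stage = "detection"
        binary, ehf_study = detect_all(
            tmean, tmax, hi, clim, study_years, cfg.definitions
        )

        stage = "indicators"
        bundle = ind.FieldBundle(
            tmean=tmean.select_years(study_years),
            tmax=tmax.select_years(study_years),
            hi=hi.select_years(study_years),
            ehf=ehf_study,
        )
        table = ind.indicator_table(
            bundle, clim, pop, study_years, pop_scaling=cfg.pop_scaling
        )

        stage = "social signal"
        tweet_binary = soc.binarize(tweets, cfg.tweet_threshold)
        norm_annual = soc.normalize_per_million(
            tweets, users, "year", mode=cfg.normalization
        )
        annual_signals = table.copy()
        tw = norm_annual.as_series()
        annual_signals.insert(
            0, "Twitter", pd.Series(tw.to_numpy(), index=tw.index.year)
        )

        stage = "correlation"
        correlations = _correlation_rows(annual_signals, mortality)

        stage = "verification"
        skill_rows = []
        frac_rows = [
            {"series": "twitter", "day_fraction": ev.heatwave_day_fraction(tweet_binary)}
        ]
        for name, series in binary.items():
            ct = ev.contingency(tweet_binary, series)
            scores = ev.skill_scores(ct)
            skill_rows.append(
                {"definition": name, "a": ct.a, "b": ct.b, "c": ct.c, "d": ct.d,
                 **scores.as_dict()}
            )
            frac_rows.append(
                {"series": name, "day_fraction": ev.heatwave_day_fraction(series)}
            )
        skill = pd.DataFrame(skill_rows)
        fractions = pd.DataFrame(frac_rows)

        stage = "output"
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "indicators.csv", float_format="%.6f")
        correlations.to_csv(outdir / "correlations.csv", index=False, float_format="%.6f")
        skill.to_csv(outdir / "skill_scores.csv", index=False, float_format="%.6f")
        fractions.to_csv(outdir / "day_fractions.csv", index=False, float_format="%.6f")
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(cfg.resolved_settings(), fh, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc

    return RunResult(
        indicators=table,
        correlations=correlations,
        skill=skill,
        day_fractions=fractions,
        binary_series={**binary, "twitter": tweet_binary},
        world=world,
    )
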