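"""A self-contained synthetic world for the heat wave pipeline.

Generates, from a single seed, every dataset the analysis consumes:

* **Climate** — daily gridded mean/max temperature and dew point over a
  30-year reference period plus an 8-year study period.  Daily mean
  temperature is a sinusoidal seasonal cycle plus a regionally shared
  AR(1) anomaly plus independent per-pixel noise; multi-day heat
  episodes (Poisson count per study year, geometric length, constant
  intensity, rectangular pixel footprint) are added on top during the
  warm season of the study years only, so the percentile baselines stay
  "pre-warming".
* **Population** — a static log-normal-ish person count per pixel.
* **Social signal** — quarterly active users growing logistically, and
  daily tweet counts: a Poisson background plus, on days of positive
  heat impact, a heavy-tailed burst whose mean is the latent impact
  times a Pareto draw, the coupling constant and the current user base
  (so that normalising by users recovers the heat signal).
* **Mortality** — monthly deaths accumulating the same latent impact,
  ``round(scale * sum_days (exp(k * exposure) - 1))`` plus optional
  non-negative reporting noise, observed through three synthetic
  "sources" (one with monthly detail, two annual-only with
  multiplicative reporting error).

Tweets and deaths are thus two noisy observations of one latent daily
impact process — the structural reason the social signal tracks
mortality better than any single climatic summary of the fields.

Exposure is the population-weighted mean positive exceedance of daily
mean temperature over its pooled reference-period 95th percentile, in
degC — the per-capita analogue of the population-scaled indicators.

All randomness flows from ``SyntheticConfig.seed`` through named
substreams (climate / population / social / mortality), so regenerating
one stage never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import FieldSeries, GridDefinition, compute_climatology
from .evaluation import MortalityTable
from .indicators import PopulationGrid
from .social import ActiveUserSeries, TweetCountSeries

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "ClimateBundle",
    "generate_climate",
    "generate_population",
    "generate_social",
    "generate_mortality",
    "generate_world",
    "compute_exposure",
    "power_law_sample",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world (defaults are the study conditions).

    Temperatures in degC, rates per day or per year as noted.  The
    default grid is 8x8 pixels at 0.75 degrees; the default calendar is
    a 30-year reference period (1980-2009) followed by an 8-year study
    period (2010-2017).
    """

    seed: int = 0
    nlat: int = 8
    nlon: int = 8
    resolution: float = 0.75
    lat0: float = 15.0
    lon0: float = 75.0
    start_year: int = 1980
    years_climatology: int = 30
    years_study: int = 8

    base_tmean: float = 27.0          # annual-mean daily mean temperature
    seasonal_amplitude: float = 8.0   # half peak-to-trough seasonal swing
    peak_doy: int = 135               # mid-May pre-monsoon peak
    ar1_rho: float = 0.7              # persistence of the regional anomaly
    noise_sd: float = 1.5             # innovation SD of the regional anomaly
    pixel_noise_sd: float = 0.8       # independent per-pixel daily noise
    pixel_offset_sd: float = 2.0      # static climatological spread across pixels

    episode_rate: float = 3.0         # heat episodes per study year
    episode_mean_length: float = 5.0  # mean length, days (min 2: episodes are multi-day)
    episode_intensity: float = 4.0    # added degC during an episode
    episode_window: int = 30          # episodes start within +- this many days of the peak
    episode_max_extent: int = 5       # max footprint side length, pixels

    tmax_offset_mean: float = 7.0     # diurnal range proxy: Tmax - Tmean
    tmax_offset_sd: float = 1.0
    dewpoint_depression_mean: float = 8.0
    dewpoint_depression_sd: float = 3.0

    population_total: float = 5.0e8   # persons on the grid
    population_sigma: float = 2.0     # lognormal spread: population is concentrated

    tweet_baseline_rate: float = 0.2  # background tweets/day at full user base
    tweet_coupling: float = 10.0      # burst tweets per unit of daily impact
    tweet_tail_exponent: float = 3.5  # power-law density exponent of burst sizes
    users_start: float = 30e6
    users_end: float = 330e6

    mortality_scale: float = 1.5      # deaths per unit of exponential excess heat
    mortality_exponent: float = 1.2   # per degC of exposure
    mortality_noise_rate: float = 0.5  # Poisson reporting noise per month
    source_noise_sd: float = 0.15     # lognormal sigma of annual-only sources

    def __post_init__(self) -> None:
        bad = []
        if self.seed < 0:
            bad.append("seed")
        for name in (
            "episode_rate",
            "tweet_baseline_rate",
            "tweet_coupling",
            "mortality_scale",
            "mortality_noise_rate",
            "noise_sd",
            "pixel_noise_sd",
        ):
            if getattr(self, name) < 0:
                bad.append(name)
        if not 0.0 <= self.ar1_rho < 1.0:
            bad.append("ar1_rho")
        if self.tweet_tail_exponent <= 1.0:
            bad.append("tweet_tail_exponent")
        if self.users_start <= 0 or self.users_end <= 0:
            bad.append("users_start/users_end")
        if self.nlat < 1 or self.nlon < 1:
            bad.append("nlat/nlon")
        if bad:
            raise ValueError(f"invalid synthetic config fields: {bad}")

    @property
    def reference_period(self) -> tuple[int, int]:
        return (self.start_year, self.start_year + self.years_climatology - 1)

    @property
    def study_period(self) -> tuple[int, int]:
        y0 = self.start_year + self.years_climatology
        return (y0, y0 + self.years_study - 1)

    def grid(self) -> GridDefinition:
        lat = self.lat0 + self.resolution * np.arange(self.nlat)
        lon = self.lon0 + self.resolution * np.arange(self.nlon)
        return GridDefinition(lat=lat, lon=lon, resolution=self.resolution)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """A named substream: stable across runs and independent per stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


@dataclass(eq=False)
class ClimateBundle:
    tmean: FieldSeries
    tmax: FieldSeries
    tdew: FieldSeries
    truth: pd.Series  # per study day: an inserted episode is active somewhere
    episodes: list[dict]


def generate_climate(cfg: SyntheticConfig) -> ClimateBundle:
    """Daily gridded temperature fields with inserted heat episodes."""
    rng = _rng(cfg.seed, "climate")
    grid = cfg.grid()
    y0 = cfg.start_year
    y_end = cfg.study_period[1]
    times = pd.date_range(f"{y0}-01-01", f"{y_end}-12-31", freq="D")
    n = len(times)
    doy = times.day_of_year.to_numpy()

    seasonal = cfg.base_tmean + cfg.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - cfg.peak_doy) / 365.25
    )
    # regional AR(1) anomaly shared by all pixels
    innov = rng.normal(0.0, cfg.noise_sd, size=n)
    anom = np.empty(n)
    acc = 0.0
    rho = cfg.ar1_rho
    for i in range(n):  # short loop; scipy.lfilter is overkill here
        acc = rho * acc + innov[i]
        anom[i] = acc
    pixel_noise = rng.normal(0.0, cfg.pixel_noise_sd, size=(n, cfg.nlat, cfg.nlon))
    # static spatial climatology: some pixels are systematically hotter, so the
    # region-wide absolute maximum is owned by a few hot pixels and varies
    # little with the inserted episodes (per-pixel percentile baselines absorb
    # the offsets)
    pixel_offset = rng.normal(0.0, cfg.pixel_offset_sd, size=(cfg.nlat, cfg.nlon))
    tmean = (
        seasonal[:, None, None]
        + anom[:, None, None]
        + pixel_offset[None, :, :]
        + pixel_noise
    )

    # heat episodes in the study years only, in the warm season
    truth = np.zeros(n, dtype=bool)
    episodes: list[dict] = []
    sy0, sy1 = cfg.study_period
    year_of = times.year.to_numpy()
    for year in range(sy0, sy1 + 1):
        n_ep = rng.poisson(cfg.episode_rate)
        year_idx = np.flatnonzero(year_of == year)
        for _ in range(n_ep):
            start_doy = int(
                rng.integers(cfg.peak_doy - cfg.episode_window, cfg.peak_doy + cfg.episode_window + 1)
            )
            # 1 + geometric: episodes are at least two days long (a one-day
            # spike is not a heat wave and the 2-day detectors cannot see it)
            length = 1 + int(rng.geometric(1.0 / (cfg.episode_mean_length - 1.0)))
            i0 = year_idx[0] + start_doy - 1
            i1 = min(i0 + length, n)
            if i0 >= n:
                continue
            h = int(rng.integers(2, min(cfg.episode_max_extent, cfg.nlat) + 1))
            w = int(rng.integers(2, min(cfg.episode_max_extent, cfg.nlon) + 1))
            r0 = int(rng.integers(0, cfg.nlat - h + 1))
            c0 = int(rng.integers(0, cfg.nlon - w + 1))
            tmean[i0:i1, r0 : r0 + h, c0 : c0 + w] += cfg.episode_intensity
            truth[i0:i1] = True
            episodes.append(
                {
                    "year": year,
                    "start": times[i0],
                    "length": i1 - i0,
                    "rows": (r0, r0 + h),
                    "cols": (c0, c0 + w),
                    "intensity": cfg.episode_intensity,
                }
            )

    offset = np.clip(
        rng.normal(cfg.tmax_offset_mean, cfg.tmax_offset_sd, size=tmean.shape), 0.1, None
    )
    depression = np.clip(
        rng.normal(
            cfg.dewpoint_depression_mean, cfg.dewpoint_depression_sd, size=tmean.shape
        ),
        0.0,
        None,
    )
    tmax = tmean + offset
    tdew = tmean - depression

    study_sel = (year_of >= sy0) & (year_of <= sy1)
    truth_series = pd.Series(truth[study_sel], index=times[study_sel], name="episode")
    return ClimateBundle(
        tmean=FieldSeries(grid, times, "T_mean", tmean),
        tmax=FieldSeries(grid, times, "T_max", tmax),
        tdew=FieldSeries(grid, times, "T_dew", tdew),
        truth=truth_series,
        episodes=episodes,
    )


def generate_population(cfg: SyntheticConfig) -> PopulationGrid:
    """A static, spatially heterogeneous person count per pixel."""
    rng = _rng(cfg.seed, "population")
    raw = rng.lognormal(mean=0.0, sigma=cfg.population_sigma, size=(cfg.nlat, cfg.nlon))
    persons = raw / raw.sum() * cfg.population_total
    return PopulationGrid(cfg.grid(), persons)


def compute_exposure(
    tmean: FieldSeries,
    pop: PopulationGrid,
    reference_period: tuple[int, int],
    study_period: tuple[int, int],
) -> pd.Series:
    """Per-capita population-weighted positive T exceedance (degC) per study day."""
    clim = compute_climatology(tmean, reference_period, levels=(0.95,))
    p95 = clim.percentiles[0.95]
    sel = np.asarray(
        (tmean.times.year >= study_period[0]) & (tmean.times.year <= study_period[1])
    )
    m = tmean.grid.mask
    pos = np.maximum(0.0, tmean.values[sel][:, m] - p95[m][None, :])
    w = pop.persons[m]
    exposure = (pos * w[None, :]).sum(axis=1) / w.sum()
    return pd.Series(exposure, index=tmean.times[sel], name="exposure")


def daily_impact(cfg: SyntheticConfig, exposure: pd.Series) -> np.ndarray:
    """Latent daily heat impact: ``exp(k * exposure) - 1``.

    Zero on zero-exposure days; sharply convex in exposure.  Both the
    tweet bursts and the death counts are driven by this same latent
    process — social attention and mortality are modelled as two noisy
    observations of one impact variable, which is what lets the social
    signal out-predict any single climatic summary of the temperature
    field.
    """
    return np.exp(cfg.mortality_exponent * exposure.to_numpy()) - 1.0


def power_law_sample(rng: np.random.Generator, alpha: float, size: int) -> np.ndarray:
    """Pareto draws with density exponent ``alpha`` (support x >= 1).

    Inverse-transform: ``X = U ** (-1/(alpha-1))`` so the survival
    function is ``P(X > x) = x ** -(alpha - 1)``.
    """
    if alpha <= 1.0:
        raise ValueError("tail exponent must exceed 1")
    u = rng.uniform(size=size)
    return u ** (-1.0 / (alpha - 1.0))


def generate_social(
    cfg: SyntheticConfig, exposure: pd.Series
) -> tuple[TweetCountSeries, ActiveUserSeries]:
    """Quarterly users and a daily tweet count series coupled to exposure.

    Both the Poisson background and the exposure-driven bursts scale
    with the current user base relative to its final value, so raw
    counts carry the platform-growth trend that per-user normalisation
    is meant to remove.
    """
    rng = _rng(cfg.seed, "social")
    dates = pd.DatetimeIndex(exposure.index)
    q_start = pd.Timestamp(dates[0]).to_period("Q").start_time
    # one knot past the last day so every study day interpolates
    q_end = (pd.Timestamp(dates[-1]).to_period("Q") + 1).start_time
    quarters = pd.date_range(q_start, q_end, freq="QS")
    tau = np.linspace(0.0, 1.0, len(quarters))
    k = 6.0
    sig = 1.0 / (1.0 + np.exp(-k * (tau - 0.5)))
    sig = (sig - sig[0]) / (sig[-1] - sig[0])
    users = ActiveUserSeries(quarters, cfg.users_start + (cfg.users_end - cfg.users_start) * sig)

    daily_users = np.interp(
        dates.asi8.astype(float),
        quarters.asi8.astype(float),
        users.users,
    )
    scale = daily_users / cfg.users_end
    counts = rng.poisson(cfg.tweet_baseline_rate * scale)
    impact = daily_impact(cfg, exposure)
    hot = impact > 0
    counts = counts.astype(np.int64)
    if cfg.tweet_coupling > 0 and hot.any():
        bursts = power_law_sample(rng, cfg.tweet_tail_exponent, int(hot.sum()))
        counts[hot] += rng.poisson(
            cfg.tweet_coupling * impact[hot] * scale[hot] * bursts
        ).astype(np.int64)
    return (
        TweetCountSeries(dates, counts.astype(np.int64), query_label="synthetic heat wave"),
        users,
    )


def generate_mortality(
    cfg: SyntheticConfig, exposure: pd.Series, *, noise: bool = True
) -> MortalityTable:
    """Monthly and annual death tables, exponential in daily exposure.

    The primary source ``synthetic-monthly`` carries both monthly and
    annual rows; ``synthetic-annual-a``/``-b`` observe the same latent
    annual totals through multiplicative lognormal reporting error.
    """
    rng = _rng(cfg.seed, "mortality")
    s = pd.Series(daily_impact(cfg, exposure), index=exposure.index)
    monthly = cfg.mortality_scale * s.resample("MS").sum()
    deaths_m = np.rint(monthly.to_numpy()).astype(int)
    if noise:
        deaths_m = deaths_m + rng.poisson(cfg.mortality_noise_rate, size=deaths_m.size)
    monthly_deaths = pd.Series(deaths_m, index=monthly.index)
    annual_latent = monthly_deaths.resample("YS").sum()

    rows = []
    for ts, v in monthly_deaths.items():
        rows.append(
            {"period": f"{ts.year}-{ts.month:02d}", "region": "synthetic-region",
             "source": "synthetic-monthly", "deaths": int(v)}
        )
    for ts, v in annual_latent.items():
        rows.append(
            {"period": str(ts.year), "region": "synthetic-region",
             "source": "synthetic-monthly", "deaths": int(v)}
        )
    for label in ("synthetic-annual-a", "synthetic-annual-b"):
        for ts, v in annual_latent.items():
            obs = float(v)
            if noise:
                obs *= rng.lognormal(0.0, cfg.source_noise_sd)
            rows.append(
                {"period": str(ts.year), "region": "synthetic-region",
                 "source": label, "deaths": int(round(obs))}
            )
    return MortalityTable(pd.DataFrame(rows))


@dataclass(eq=False)
class SyntheticWorld:
    config: SyntheticConfig
    climate: ClimateBundle
    population: PopulationGrid
    users: ActiveUserSeries
    tweets: TweetCountSeries
    mortality: MortalityTable
    exposure: pd.Series
    truth: pd.Series


def generate_world(cfg: SyntheticConfig, *, mortality_noise: bool = True) -> SyntheticWorld:
    """Generate every dataset of the synthetic study from one seed."""
    climate = generate_climate(cfg)
    pop = generate_population(cfg)
    exposure = compute_exposure(
        climate.tmean, pop, cfg.reference_period, cfg.study_period
    )
    tweets, users = generate_social(cfg, exposure)
    mortality = generate_mortality(cfg, exposure, noise=mortality_noise)
    return SyntheticWorld(
        config=cfg,
        climate=climate,
        population=pop,
        users=users,
        tweets=tweets,
        mortality=mortality,
        exposure=exposure,
        truth=climate.truth,
    )
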