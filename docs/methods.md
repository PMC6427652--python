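# Methods

This note documents the models, conventions and design choices behind
`heatsignal`, in the order the pipeline applies them.

## Derived climate fields

Relative humidity is computed from air and dew point temperature with the
Magnus-type saturation vapour pressure ratio (constants 17.625 and
243.04 °C). Because reanalysis temperature and dew point fields are rounded
independently, the dew point can nominally exceed the air temperature; RH is
clamped to [0, 100] %, and a violation larger than 0.5 °C additionally warns.
Temperatures at or below −243.04 °C (an impossible input that would zero the
denominator) raise an error.

The heat index uses the empirical nine-term polynomial in T [°F] and RH [%]
with its printed, rounded coefficients, applied without a validity-range
mask. The output is kept on the Fahrenheit scale but treated as
dimensionless. Note that the rounded coefficients differ appreciably from
the unrounded regression they descend from (at 90 °F / 50 % the rounded form
gives 116.5 where the unrounded form gives ≈ 94.6); since every use of HI in
this pipeline is relative — a percentile of HI computed from the same
polynomial — the offset cancels in detection and only the printed form is
implemented. Daily HI is computed from daily-mean temperature and daily-mean
relative humidity (averaging before, not after, the polynomial).

Sub-daily fields are collapsed to calendar days by the arithmetic mean or
maximum of each day's steps. The daily maximum of 6-hourly data understates
the true daily maximum; this is a property of the source resolution, not of
the aggregation, and is accepted as such. Incomplete days are dropped with a
warning (or raise in strict mode).

## Climatological baselines

All statistics pool **every** day of the reference period (default
1980–2009, configurable) into one per-pixel sample — no day-of-year or
seasonal stratification — so the 95th percentile of a pixel sits in its
hottest season. Percentiles interpolate linearly between the closest order
statistics; this rule is fixed so results are bit-stable. Leap days receive
no special treatment (irrelevant under pooling). Missing days in the
reference period abort with the missing ranges listed.

## Heat wave detectors

* **IMD rule** (daily max temperature TM, 30-year mean TM̄): flag when
  TM > 45 °C, or TM > TM̄+4 where TM̄ ≥ 40 °C, or TM > TM̄+5 where
  TM̄ < 40 °C. All inequalities strict; no duration filter. The source rule
  leaves TM̄ = 40 °C exactly unassigned between its two anomaly branches; it
  is assigned here to the +4 °C branch, the more conservative (more
  detecting) choice.
* **T95 / HI95**: value strictly above the pooled per-pixel 95th percentile,
  sustained for at least 2 consecutive days; shorter exceedance runs are
  removed per pixel.
* **EHF**: the excess heat factor couples a significance index (trailing
  3-day mean minus the 95th percentile of daily mean temperature) with an
  acclimatisation factor (3-day mean minus the mean of the 30 days
  immediately preceding the 3-day window, floored at 1):
  EHF = max(0, EHIsig) · max(1, EHIaccl). The window placement (trailing,
  non-overlapping) follows the EHF literature. The first 32 days of a series
  are *undefined* — excluded from day counts and fractions, not zero-filled,
  so EHF day fractions are not diluted by the warm-up.

A day is a region heat wave day when any masked-in pixel is flagged.
Raising any temperature never unflags a flagged day (monotonicity holds for
all four detectors; for EHF the acclimatisation floor guarantees it).

## Indicators and population scaling

The nine yearly indicators take the maximum over all days of the year and
all masked-in pixels. "Scaled by the affected population" is not a formula
inherited from anywhere; it is defined here as the per-day sum over pixels of
`persons × max(0, exceedance)` — the affected population being whoever
currently exceeds the threshold — maximised over the year. The alternative
reading (maximum over pixels of the per-pixel product) is available as
`pop_scaling: maxpixel`. Negative exceedances are kept in the difference
fields (TdiffM may be negative in a cool year) but contribute nothing to
population scaling. Population regridding assigns each fine cell's persons
to the coarse cell containing its centre, conserving totals exactly for
nested grids and verified to 0.1 % otherwise.

## Social signal

Daily counts from a keyword-filtered post archive are zero-filled over the
study range. The active-user normaliser is piecewise-linear interpolation of
quarterly totals (constant extrapolation at the boundaries, with a warning).
Normalised values are posts per million users; for monthly/annual periods
the default is period-total counts over period-mean users
(`normalization: period_mean`); summing daily normalised values instead is
available (`daily_sum`) — the two differ under user growth and both are
deterministic. Binarisation (default: ≥ 2 posts per day declares a heat
wave day) applies to **raw** counts, never normalised ones; the threshold is
configurable.

## Verification

The contingency table uses a = both flagged, b = candidate-only,
c = reference-only, d = neither, with the social signal as the reference and
a climate-based definition as the candidate. Under this convention Hit Rate
a/(a+c) is the fraction of reference days captured, False Alarm Rate b/(b+d)
the fraction of reference non-days falsely flagged, and Bias (a+b)/(a+c) is
identically the candidate/reference day-fraction ratio — an identity the
tests check to 1e-12, and which ties the published bias values to the
published marginal day fractions. The opposite labelling of b and c is
inconsistent with those published values (it can push the hit rate above 1),
which is why this convention is fixed and logged. Scores with a zero
denominator are reported as undefined, not silently NaN.

Correlations (Pearson, or Spearman with average ranks for ties) report
significance as 1−p with a two-sided p from the t-approximation on n−2
degrees of freedom. Zero-variance inputs yield an explicitly undefined
result. Missing periods in signal/mortality alignment are dropped pairwise
and logged; fewer than 3 aligned years makes the correlation undefined
rather than an error.

## Synthetic world

The generator supplies every input the pipeline needs, from one seed routed
through named substreams (climate / population / social / mortality), so
regenerating one stage never perturbs another and a fixed seed reproduces
the world bit for bit.

**Climate.** Daily mean temperature per pixel = annual-mean 27 °C
+ 8 °C · cos-seasonal cycle peaking at day 135 (a pre-monsoon hot season)
+ a regionally shared AR(1) anomaly (ρ = 0.7, innovation SD 1.5 °C)
+ independent per-pixel daily noise (SD 0.8 °C)
+ a static per-pixel climatological offset (SD 2 °C). The offsets make a few
pixels systematically hottest, so the region-wide absolute yearly maximum
belongs to them and varies little with impact events — the behaviour of a
large heterogeneous country — while per-pixel percentile baselines absorb
the offsets. Heat episodes are planted in the **study years only** (the
baseline period stays episode-light, i.e. baselines are "pre-warming"):
Poisson(3) episodes per year, starting within ±30 days of the seasonal peak,
length 1+geometric with mean 5 days (minimum 2 — a one-day spike is not a
heat wave and the 2-day detectors could never see it), intensity +4 °C over
a random rectangular footprint of at most 5×5 of the 8×8 pixels. Daily max
temperature adds a positive offset (mean 7 °C, SD 1 °C, clipped ≥ 0.1);
dew point subtracts a non-negative depression (mean 8, SD 3 °C — a dry
season, so the heat index adds little over temperature).

**Exposure and impact.** Daily exposure is the population-weighted mean
positive exceedance of daily mean temperature over its pooled baseline p95,
in °C. The latent daily *impact* is exp(1.2 · exposure) − 1: zero below the
threshold, sharply convex above it.

**Population** is static and concentrated (lognormal, σ = 2, total 5·10⁸),
so exposure depends on where episodes land, decoupling impact from
region-wide temperature summaries.

**Social signal.** Quarterly users grow logistically from 3·10⁷ to 3.3·10⁸
across the study period. Daily counts are Poisson background (0.2/day at
full user base) plus, on positive-impact days, a Poisson draw with mean
`10 · impact · (users/users_end) · X`, where X is Pareto with density
exponent 3.5 (heavy-tailed burst sizes with finite variance, giving the
daily counts a power-law tail). Both terms scale with the current user base,
which is precisely the trend that per-user normalisation removes.

**Mortality.** Monthly deaths = round(1.5 · Σ impact) + Poisson(0.5)
reporting noise; annual totals are sums of months. Three "sources" emulate
independent reporting: one with monthly detail, two annual-only with
multiplicative lognormal error (σ = 0.15).

Because tweets and deaths are two noisy observations of the same latent
impact process while the yearly indicators summarise only the temperature
field, the normalised social signal out-correlates the max-temperature
indicators with mortality in the large majority of seeds, the planted
episodes are recovered by the T95 detector with high recall, and switching
the coupling off collapses the tweet–mortality correlation — properties the
acceptance tests measure over 50 seeds. The zero-coupling null is evaluated
at monthly resolution (n = 96): at annual resolution (n = 8) the sampling SD
of a null correlation is ≈ 0.38, so no generator could keep |r| < 0.3
reliably.

### What the generator does not emulate

Spatial correlation of weather beyond a single shared regional mode; monsoon
humidity dynamics (dew point depression is i.i.d., so HI-based detection
carries no independent signal); user-behaviour confounders (topic popularity
drift, event-driven sign-ups, retweet cascades beyond the heavy-tailed burst
size); geolocation; reporting lags in mortality. Passing tests therefore
show the pipeline's statistical machinery is correct and that the designed
signal structure is recoverable — not that real social-media data behaves
this way.

## Problem sizes and numerical choices

Default synthetic runs use an 8×8 grid with a 30-year baseline and an 8-year
study period (≈ 13 900 days × 64 pixels), which generates and analyses in
well under a second; multi-seed experiments use 50 seeds in the tests and 20
in the acceptance script. All comparisons against thresholds are strict
inequalities; percentile interpolation is linear between order statistics;
run-length filtering scans maximal runs per pixel; CSV outputs are written
with fixed float formatting so identically seeded runs are byte-identical.

## Known limitations

The real-data path (NetCDF climate, CSV archives) is functional but exercised
only on synthetic-world exports; the heat index uses the printed rounded
coefficients by design (see above); mortality tables index periods as
strings (years or year-months), which callers must respect; the EHF warm-up
excludes the first 32 days of whatever series it is given, so callers who
want a fully defined study period must supply history (the pipeline does).
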