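# heatsignal

Heat waves kill more people than almost any other natural hazard, yet there is
no agreed quantitative definition of one: meteorological definitions threshold
temperature fields, but many of the days they flag cause no excess mortality.
`heatsignal` implements a desk-scale pipeline for studying an *impact-led*
alternative — detecting heat waves from a social-media signal (daily counts of
heat-wave-related posts, normalised by the platform's active-user base) — and
verifying conventional climate-based heat wave definitions against it.

The package is aimed at researchers in climate epidemiology and environmental
health who want to reproduce, probe or extend this comparison without access
to the original reanalysis retrievals, tweet archives and mortality reports:
a seeded synthetic world generator supplies gridded climate with planted heat
episodes, population, platform users, tweet counts and mortality with the
statistical structure the analysis assumes.

## What it computes

**Derived fields.** Relative humidity from air and dew point temperature via
the Magnus saturation-ratio formula,

    RH = 100 · exp(17.625·Td / (243.04+Td)) / exp(17.625·T / (243.04+T)),

and the empirical heat index HI(T[°F], R[%]), a nine-term polynomial
(coefficients −42.38, 2.05, 10.14, −0.22, −6.84·10⁻³, −5.48·10⁻²,
1.23·10⁻³, 8.53·10⁻⁴, −1.99·10⁻⁶).

**Four binary heat wave detectors**, per pixel, thresholded against pooled
30-year per-pixel climatology (no seasonal stratification):

| name | rule |
|------|------|
| IMD  | TM > 45 °C, or TM > TM̄+4 (TM̄ ≥ 40 °C), or TM > TM̄+5 (TM̄ < 40 °C); no duration |
| T95  | daily mean T > its 95th percentile for ≥ 2 days |
| HI95 | mean daily HI > its 95th percentile for ≥ 2 days |
| EHF  | excess heat factor EHF = max(0, T3d̄−T95) · max(1, T3d̄−T30d̄) > 0 |

A region-level day series flags a day when *any* pixel is flagged.

**Nine yearly indicators** (TmM, TMM, HIM, EHFM, TdiffM, HIdiffM and their
population-scaled variants TdiffMpop, HIdiffMpop, EHFMpop) are correlated
with annual heat-mortality tables (Pearson and Spearman, significance 1−p).

**Verification.** Each detector is scored against the binarised social signal
(≥ 2 posts/day by default) through the 2×2 contingency table (a = both,
b = candidate-only, c = reference-only, d = neither) and five skill scores:
Percentage Correct (a+d)/n, Hit Rate a/(a+c), Miss Rate c/(a+c), False Alarm
Rate b/(b+d), and frequency Bias (a+b)/(a+c).

## Worked example

```sh
heatsignal run-all --seed 1 --outdir results_demo
```

runs the full pipeline on the default synthetic world (8×8 grid at 0.75°,
30-year baseline 1980–2009, 8-year study period 2010–2017) and prints the
verification table:

```
definition   a    b  c    d  percentage_correct  hit_rate  miss_rate  false_alarm_rate  bias
       IMD 233 1036 17 1636            0.639630     0.932      0.068          0.387725 5.076
       T95 217  115 33 2557            0.949350     0.868      0.132          0.043039 1.328
      HI95 227  347 23 2325            0.873374     0.908      0.092          0.129865 2.296
       EHF 191  108 59 2564            0.942847     0.764      0.236          0.040419 1.196
```

Read: the IMD-style rule captures 93% of the social-signal heat wave days
(hit rate 0.932) but declares five times as many heat wave days as the social
reference (bias 5.08), most of them false alarms; the duration-filtered
percentile detectors (T95, EHF) are far less inflationary. The accompanying
`correlations.csv` shows the impact side — on this world the normalised post
series correlates with annual mortality at r = 0.997 while the yearly
maximum-temperature indicators TmM/TMM reach only 0.60/0.65, because deaths
follow the duration and placement of heat exposure over population, which a
yearly temperature maximum cannot see.

Four CSV tables are written (`indicators.csv`, `correlations.csv`,
`skill_scores.csv`, `day_fractions.csv`) plus `run_log.yaml` recording every
resolved methodological setting (percentile rule, EHF window placement,
contingency convention, …). `heatsignal synth` writes the raw synthetic world
(NetCDF climate + CSV tables) for use with the file-based subcommands
`detect`, `social` and `evaluate`.

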