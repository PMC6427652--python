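"""Yearly climatic indicators, including population-scaled exposure metrics.

Nine indicators per study year summarise the gridded fields:

======== =============================================================
TmM      yearly max of daily mean temperature (degC)
TMM      yearly max of daily maximum temperature (degC)
HIM      yearly max of mean daily heat index
EHFM     yearly max of the excess heat factor
TdiffM   yearly max of (daily mean T - its pooled p95)
HIdiffM  yearly max of (mean daily HI - its pooled p95)
TdiffMpop   yearly max of the daily population-weighted positive
            T exceedance (person degC)
HIdiffMpop  same for the heat index exceedance
EHFMpop  yearly max of the daily population-weighted EHF
======== =============================================================

"Scaled by the affected population" is implemented as the sum over
pixels of ``population * max(0, exceedance)`` per day — the affected
population is whoever currently exceeds the threshold — maximised over
the year.  An alternative reading (max over pixels of the per-pixel
product) is available via ``pop_scaling="maxpixel"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimatologyStats, FieldSeries, GridDefinition

__all__ = [
    "PopulationGrid",
    "FieldBundle",
    "INDICATOR_COLUMNS",
    "regrid_population",
    "yearly_max",
    "exceedance",
    "population_scaled_daily",
    "indicator_table",
]

INDICATOR_COLUMNS = (
    "TmM",
    "TMM",
    "HIM",
    "EHFM",
    "TdiffM",
    "HIdiffM",
    "TdiffMpop",
    "HIdiffMpop",
    "EHFMpop",
)


@dataclass(eq=False)
class PopulationGrid:
    """Person counts per grid cell."""

    grid: GridDefinition
    persons: np.ndarray

    def __post_init__(self) -> None:
        self.persons = np.asarray(self.persons, dtype=float)
        if self.persons.shape != self.grid.shape:
            raise ValueError("persons shape does not match grid")
        if np.any(self.persons < 0):
            raise ValueError("population must be non-negative")
        if self.persons.sum() <= 0:
            raise ValueError("total population must be positive")

    @property
    def total(self) -> float:
        return float(self.persons.sum())


@dataclass(eq=False)
class FieldBundle:
    """The daily fields an indicator table is built from."""

    tmean: FieldSeries
    tmax: FieldSeries
    hi: FieldSeries
    ehf: FieldSeries

    def __post_init__(self) -> None:
        g = self.tmean.grid
        for fs in (self.tmax, self.hi, self.ehf):
            g.require_same(fs.grid)


def regrid_population(pop_fine: PopulationGrid, target: GridDefinition) -> PopulationGrid:
    """Conservatively regrid person counts onto a coarser grid.

    Each fine cell's persons are assigned to the target cell containing
    the fine cell centre, so the total is conserved exactly whenever
    every fine centre falls inside the target domain (the nested
    integer-ratio case of 0.25 -> 0.75 degrees in particular).
    """
    if pop_fine.grid.same_as(target):
        return PopulationGrid(target, pop_fine.persons.copy())
    half = target.resolution / 2.0

    def cell_index(centers: np.ndarray, pts: np.ndarray) -> np.ndarray:
        idx = np.abs(pts[:, None] - centers[None, :]).argmin(axis=1)
        inside = np.abs(pts - centers[idx]) <= half + 1e-9
        return np.where(inside, idx, -1)

    li = cell_index(target.lat, pop_fine.grid.lat)
    lj = cell_index(target.lon, pop_fine.grid.lon)
    if np.all(li < 0) or np.all(lj < 0):
        raise ValueError("fine and target population domains are disjoint")
    out = np.zeros(target.shape, dtype=float)
    for i, ti in enumerate(li):
        if ti < 0:
            continue
        for j, tj in enumerate(lj):
            if tj < 0:
                continue
            out[ti, tj] += pop_fine.persons[i, j]
    result = PopulationGrid(target, out)
    if abs(result.total - pop_fine.total) > 1e-3 * pop_fine.total:
        raise ValueError(
            "population not conserved under regridding: "
            f"{pop_fine.total:.0f} -> {result.total:.0f}"
        )
    return result


def yearly_max(fs: FieldSeries, year: int) -> float:
    """Max over all days of ``year`` and all masked-in pixels (NaN skipped)."""
    sel = np.asarray(fs.times.year == int(year))
    if not sel.any():
        raise ValueError(f"year {year} absent from field series")
    vals = fs.values[sel][:, fs.grid.mask]
    if np.all(np.isnan(vals)):
        raise ValueError(f"year {year} has no defined values")
    return float(np.nanmax(vals))


def exceedance(fs: FieldSeries, threshold: np.ndarray) -> FieldSeries:
    """Difference field value - threshold per pixel/day (may be negative)."""
    threshold = np.asarray(threshold, dtype=float)
    if threshold.shape != fs.grid.shape:
        raise ValueError("threshold shape does not match grid")
    return FieldSeries(
        fs.grid, fs.times, f"{fs.variable}_diff", fs.values - threshold[None, :, :]
    )


def population_scaled_daily(
    diff: FieldSeries, pop: PopulationGrid, *, mode: str = "sum"
) -> pd.Series:
    """Daily population-weighted positive exceedance.

    ``mode="sum"``: sum over masked-in pixels of persons * max(0, diff).
    ``mode="maxpixel"``: max over pixels of the same product.
    NaN days (detector warm-up) map to NaN.
    """
    diff.grid.require_same(pop.grid)
    if mode not in ("sum", "maxpixel"):
        raise ValueError(f"unknown pop_scaling mode {mode!r}")
    m = diff.grid.mask
    pos = np.maximum(0.0, diff.values[:, m])
    weighted = pos * pop.persons[m][None, :]
    nan_day = np.all(np.isnan(diff.values[:, m]), axis=1)
    out = weighted.sum(axis=1) if mode == "sum" else weighted.max(axis=1)
    out = out.astype(float)
    out[nan_day] = np.nan
    return pd.Series(out, index=diff.times, name=f"{diff.variable}_pop")


def indicator_table(
    bundle: FieldBundle,
    clim: ClimatologyStats,
    pop: PopulationGrid,
    years: list[int],
    *,
    pop_scaling: str = "sum",
) -> pd.DataFrame:
    """Assemble the nine yearly indicators, one row per study year."""
    bundle.tmean.grid.require_same(clim.grid)
    bundle.tmean.grid.require_same(pop.grid)
    tdiff = exceedance(bundle.tmean, clim.p95_tmean)
    hidiff = exceedance(bundle.hi, clim.p95_hi)
    tdiff_pop = population_scaled_daily(tdiff, pop, mode=pop_scaling)
    hidiff_pop = population_scaled_daily(hidiff, pop, mode=pop_scaling)
    # EHF is already a positive-part quantity; weight it directly.
    ehf_pop = population_scaled_daily(bundle.ehf, pop, mode=pop_scaling)

    rows = []
    for year in years:
        year = int(year)
        sel_ehf = ehf_pop[ehf_pop.index.year == year]
        rows.append(
            {
                "year": year,
                "TmM": yearly_max(bundle.tmean, year),
                "TMM": yearly_max(bundle.tmax, year),
                "HIM": yearly_max(bundle.hi, year),
                "EHFM": yearly_max(bundle.ehf, year),
                "TdiffM": yearly_max(tdiff, year),
                "HIdiffM": yearly_max(hidiff, year),
                "TdiffMpop": float(tdiff_pop[tdiff_pop.index.year == year].max()),
                "HIdiffMpop": float(hidiff_pop[hidiff_pop.index.year == year].max()),
                "EHFMpop": float(sel_ehf.max(skipna=True)),
            }
        )
    table = pd.DataFrame(rows).set_index("year")
    if not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("indicator table contains non-finite entries")
    return table[list(INDICATOR_COLUMNS)]
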