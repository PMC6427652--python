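"""Gridded climate fields: humidity, heat index, daily aggregation, climatology.

This module owns the in-memory containers for regular lat/lon gridded
time series (:class:`GridDefinition`, :class:`FieldSeries`) and the
per-pixel climatological baselines (:class:`Climatology`,
:class:`ClimatologyStats`) that the heat wave detectors threshold
against.

Conventions
-----------
* Temperatures are degrees Celsius unless a function name says
  otherwise; relative humidity is percent; the heat index is the raw
  output of the empirical Fahrenheit-input polynomial and is treated as
  dimensionless.
* Field values are stored as ``(time, lat, lon)`` float arrays; a
  boolean pixel mask on the grid marks the study region.
* Climatological statistics pool **all** calendar days of the reference
  period into one per-pixel sample — no day-of-year or seasonal
  stratification — so a pixel's 95th percentile is dominated by its
  hottest season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridDefinition",
    "FieldSeries",
    "Climatology",
    "ClimatologyStats",
    "relative_humidity",
    "heat_index",
    "heat_index_celsius",
    "celsius_to_fahrenheit",
    "daily_aggregate",
    "compute_climatology",
    "build_climatology_stats",
    "read_fields_netcdf",
    "field_to_dataarray",
    "write_fields_netcdf",
    "climatology_to_frame",
]

# Magnus-type saturation vapour pressure constants (over water).
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # degC

# Coefficients of the empirical heat index polynomial, in the order
# 1, T, R, T*R, T^2, R^2, T^2*R, T*R^2, T^2*R^2 with T in degF, R in %.
_HI_COEFFS = (
    -42.38,
    2.05,
    10.14,
    -0.22,
    -6.84e-3,
    -5.48e-2,
    1.23e-3,
    8.53e-4,
    -1.99e-6,
)


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    return arr


@dataclass(frozen=True, eq=False)
class GridDefinition:
    """A regular lat/lon grid with a boolean study-region mask.

    Parameters
    ----------
    lat, lon : 1-D arrays of cell-centre coordinates in degrees.  The
        spacing must be uniform to within 1e-9 of ``resolution``; the
        latitude axis may run in either direction.
    resolution : grid spacing in degrees (same for both axes).
    mask : optional ``(nlat, nlon)`` boolean array, True for pixels
        inside the study region.  Defaults to all-True.
    """

    lat: np.ndarray
    lon: np.ndarray
    resolution: float
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = _as_1d(self.lat, "lat")
        lon = _as_1d(self.lon, "lon")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, ax in (("lat", lat), ("lon", lon)):
            if ax.size > 1:
                steps = np.abs(np.diff(ax))
                if np.any(np.abs(steps - self.resolution) > 1e-9):
                    raise ValueError(
                        f"{name} spacing is not uniform at resolution "
                        f"{self.resolution}"
                    )
        mask = self.mask
        if mask is None:
            mask = np.ones((lat.size, lon.size), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lat.size, lon.size):
            raise ValueError("mask shape does not match (nlat, nlon)")
        if not mask.any():
            raise ValueError("mask must contain at least one pixel")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def same_as(self, other: "GridDefinition") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
            and bool(np.all(self.mask == other.mask))
        )

    def require_same(self, other: "GridDefinition") -> None:
        if not self.same_as(other):
            raise ValueError("grid mismatch between operands")


@dataclass(eq=False)
class FieldSeries:
    """A time series of one gridded variable, shape ``(time, lat, lon)``.

    ``times`` must be strictly increasing without duplicates.  Undefined
    values (e.g. the warm-up window of the excess heat factor) are NaN.
    """

    grid: GridDefinition
    times: pd.DatetimeIndex
    variable: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        if len(self.times) == 0:
            raise ValueError("times must be non-empty")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ValueError("times must be strictly increasing, no duplicates")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.times),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (time, lat, lon) {expected}"
            )

    @property
    def n_times(self) -> int:
        return len(self.times)

    def masked(self) -> np.ndarray:
        """Values of masked-in pixels as an ``(ntime, npix)`` array."""
        return self.values[:, self.grid.mask]

    def select_years(self, years: Iterable[int]) -> "FieldSeries":
        yrs = set(int(y) for y in years)
        sel = self.times.year.isin(sorted(yrs))
        if not sel.any():
            raise ValueError(f"no data for years {sorted(yrs)}")
        return FieldSeries(self.grid, self.times[sel], self.variable, self.values[sel])


def _sat_vapour_ratio(t: np.ndarray) -> np.ndarray:
    return np.exp(_MAGNUS_A * t / (_MAGNUS_B + t))


def relative_humidity(t_air, t_dew, *, tolerance: float = 0.5):
    """Relative humidity (%) from air and dew point temperature (degC).

    Uses the Magnus-type saturation vapour pressure ratio

    ``RH = 100 * exp(17.625*Td/(243.04+Td)) / exp(17.625*T/(243.04+T))``

    elementwise.  Dew points exceeding the air temperature by more than
    ``tolerance`` degC (an artifact of independently rounded reanalysis
    fields) trigger a warning; all results are clamped to [0, 100].
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    if np.any(t_air <= -_MAGNUS_B) or np.any(t_dew <= -_MAGNUS_B):
        raise ValueError(f"temperatures must exceed {-_MAGNUS_B} degC")
    excess = t_dew - t_air
    if np.any(excess > tolerance):
        warnings.warn(
            "dew point exceeds air temperature by more than "
            f"{tolerance} degC on {int(np.sum(excess > tolerance))} values; "
            "clamping relative humidity to 100%",
            stacklevel=2,
        )
    rh = 100.0 * _sat_vapour_ratio(t_dew) / _sat_vapour_ratio(t_air)
    return np.clip(rh, 0.0, 100.0)


def heat_index(t_fahrenheit, rh):
    """Empirical heat index from temperature (degF) and humidity (%).

    Nine-term bilinear-quadratic polynomial in T and R; the output is
    on the Fahrenheit scale but conventionally treated as dimensionless.
    No validity-range masking is applied.
    """
    t = np.asarray(t_fahrenheit, dtype=float)
    r = np.asarray(rh, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("heat_index inputs must be finite")
    c = _HI_COEFFS
    return (
        c[0]
        + c[1] * t
        + c[2] * r
        + c[3] * t * r
        + c[4] * t * t
        + c[5] * r * r
        + c[6] * t * t * r
        + c[7] * t * r * r
        + c[8] * t * t * r * r
    )


def celsius_to_fahrenheit(t_c):
    return np.asarray(t_c, dtype=float) * 1.8 + 32.0


def heat_index_celsius(t_celsius, rh):
    """Convenience wrapper: convert degC to degF before the polynomial."""
    return heat_index(celsius_to_fahrenheit(t_celsius), rh)


def daily_aggregate(sub_daily: FieldSeries, stat: str, *, strict: bool = False) -> FieldSeries:
    """Collapse a sub-daily field to one value per calendar day.

    ``stat`` is ``"mean"`` or ``"max"``.  Days with fewer time steps
    than the most common per-day count are dropped (with a warning) by
    default, or raise in ``strict`` mode.  Day boundaries are taken at
    00:00 in the data's own time reference.
    """
    if stat not in ("mean", "max"):
        raise ValueError(f"unknown stat {stat!r}")
    dates = sub_daily.times.normalize()
    counts = pd.Series(1, index=dates).groupby(level=0).sum()
    expected = int(counts.max())
    incomplete = counts.index[counts < expected]
    if len(incomplete):
        if strict:
            raise ValueError(
                f"incomplete days (fewer than {expected} steps): "
                f"{[d.date().isoformat() for d in incomplete]}"
            )
        warnings.warn(
            f"dropping {len(incomplete)} incomplete day(s) with fewer than "
            f"{expected} steps",
            stacklevel=2,
        )
    keep = ~dates.isin(incomplete)
    vals = sub_daily.values[np.asarray(keep)]
    kept_dates = dates[keep]
    n_days = len(counts) - len(incomplete)
    blocks = vals.reshape(n_days, expected, *sub_daily.grid.shape)
    out = blocks.mean(axis=1) if stat == "mean" else blocks.max(axis=1)
    day_index = pd.DatetimeIndex(kept_dates.unique())
    return FieldSeries(sub_daily.grid, day_index, sub_daily.variable, out)


@dataclass(eq=False)
class Climatology:
    """Per-pixel pooled statistics of one variable over a reference period."""

    grid: GridDefinition
    reference_period: tuple[int, int]
    variable: str
    mean: np.ndarray
    percentiles: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.grid.mask
        if not np.all(np.isfinite(self.mean[m])):
            raise ValueError("non-finite climatological mean inside mask")
        for lvl, arr in self.percentiles.items():
            if not np.all(np.isfinite(arr[m])):
                raise ValueError(f"non-finite percentile {lvl} inside mask")
        if 0.5 in self.percentiles and 0.95 in self.percentiles:
            if np.any(self.percentiles[0.95][m] < self.percentiles[0.5][m]):
                raise ValueError("p95 < p50: percentile ordering violated")


def _missing_ranges(required: pd.DatetimeIndex, have: pd.DatetimeIndex) -> list[str]:
    missing = required.difference(have)
    if missing.empty:
        return []
    out: list[str] = []
    start = prev = missing[0]
    for d in missing[1:]:
        if (d - prev).days > 1:
            out.append(f"{start.date()}..{prev.date()}")
            start = d
        prev = d
    out.append(f"{start.date()}..{prev.date()}")
    return out


def compute_climatology(
    daily: FieldSeries,
    reference_period: tuple[int, int] = (1980, 2009),
    levels: Sequence[float] = (0.5, 0.95),
) -> Climatology:
    """Pool all reference-period days per pixel; return mean and percentiles.

    Percentiles use linear interpolation between the closest order
    statistics.  Every calendar day of the reference period must be
    present; otherwise the missing ranges are reported in the error.
    """
    y0, y1 = int(reference_period[0]), int(reference_period[1])
    if y1 < y0:
        raise ValueError("reference period end before start")
    for lvl in levels:
        if not 0.0 < lvl < 1.0:
            raise ValueError(f"percentile level {lvl} outside (0, 1)")
    required = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    gaps = _missing_ranges(required, daily.times.normalize())
    if gaps:
        raise ValueError(f"reference period not fully covered; missing {gaps}")
    sel = (daily.times.year >= y0) & (daily.times.year <= y1)
    sample = daily.values[np.asarray(sel)]
    mean = sample.mean(axis=0)
    pct = {
        float(lvl): np.percentile(sample, 100.0 * lvl, axis=0, method="linear")
        for lvl in levels
    }
    return Climatology(daily.grid, (y0, y1), daily.variable, mean, pct)


@dataclass(eq=False)
class ClimatologyStats:
    """The baseline statistics the heat wave detectors consume.

    ``mean_tmax`` feeds the IMD-style absolute/anomaly rule,
    ``p95_tmean`` the T95 detector and the excess heat factor,
    ``p95_hi`` the HI95 detector.
    """

    grid: GridDefinition
    reference_period: tuple[int, int]
    mean_tmax: np.ndarray
    p95_tmean: np.ndarray
    p95_hi: np.ndarray


def build_climatology_stats(
    tmax_daily: FieldSeries,
    tmean_daily: FieldSeries,
    hi_daily: FieldSeries,
    reference_period: tuple[int, int] = (1980, 2009),
) -> ClimatologyStats:
    """Compute the detector baselines from daily max T, mean T and mean HI."""
    tmax_daily.grid.require_same(tmean_daily.grid)
    tmax_daily.grid.require_same(hi_daily.grid)
    c_tmax = compute_climatology(tmax_daily, reference_period, levels=(0.95,))
    c_tmean = compute_climatology(tmean_daily, reference_period, levels=(0.5, 0.95))
    c_hi = compute_climatology(hi_daily, reference_period, levels=(0.5, 0.95))
    return ClimatologyStats(
        grid=tmax_daily.grid,
        reference_period=(int(reference_period[0]), int(reference_period[1])),
        mean_tmax=c_tmax.mean,
        p95_tmean=c_tmean.percentiles[0.95],
        p95_hi=c_hi.percentiles[0.95],
    )


# ---------------------------------------------------------------------------
# NetCDF / tabular I/O


def field_to_dataarray(fs: FieldSeries) -> xr.DataArray:
    return xr.DataArray(
        fs.values,
        coords={"time": fs.times, "lat": fs.grid.lat, "lon": fs.grid.lon},
        dims=("time", "lat", "lon"),
        name=fs.variable,
    )


def write_fields_netcdf(fields: Iterable[FieldSeries], path: str | Path) -> None:
    """Write one or more field series to a classic-format NetCDF file."""
    ds = xr.Dataset({fs.variable: field_to_dataarray(fs) for fs in fields})
    ds.to_netcdf(path, engine="scipy")


def read_fields_netcdf(
    path: str | Path,
    variables: Mapping[str, str],
    *,
    resolution: float | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, FieldSeries]:
    """Read named variables from a CF-style NetCDF file.

    ``variables`` maps the file's variable names to the canonical names
    used downstream (e.g. ``{"t2m": "T_mean"}``).  The grid resolution
    is inferred from the coordinate spacing unless given.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        res = resolution
        if res is None:
            axis = lat if lat.size > 1 else lon
            res = float(np.abs(np.diff(axis)).mean())
        grid = GridDefinition(lat=lat, lon=lon, resolution=res, mask=mask)
        times = pd.DatetimeIndex(ds["time"].values)
        out: dict[str, FieldSeries] = {}
        for file_var, name in variables.items():
            vals = np.asarray(ds[file_var].values, dtype=float)
            out[name] = FieldSeries(grid, times, name, vals)
    return out


def climatology_to_frame(clim: Climatology) -> pd.DataFrame:
    """Flatten a climatology to rows (pixel, lat, lon, stat, value)."""
    nlat, nlon = clim.grid.shape
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    rows = []
    stats: list[tuple[str, np.ndarray]] = [("mean", clim.mean)]
    stats += [(f"p{int(round(lvl * 100)):02d}", arr) for lvl, arr in sorted(clim.percentiles.items())]
    for stat_name, arr in stats:
        rows.append(
            pd.DataFrame(
                {
                    "pixel": ii.ravel() * nlon + jj.ravel(),
                    "lat": clim.grid.lat[ii.ravel()],
                    "lon": clim.grid.lon[jj.ravel()],
                    "stat": stat_name,
                    "value": arr.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
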