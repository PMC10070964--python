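"""Derived epidemiological covariates.

From daily or monthly climate fields this module computes the covariates
commonly fed to vector-borne-disease models: growing degree days (GDD), the
De Martonne aridity index P/(T+10), rainy-day counts, windowed variability
(standard deviation and excess kurtosis) of raster time series, the 19
standard bioclimatic variables (BIO1..BIO19, as defined by the classic
``biovars`` summaries of monthly tmin/tmax/precipitation), and per-zone
land-cover percentage tables.

All per-pixel operations are vectorized: the monthly inputs may be scalars
per month (shape ``(12,)``) or raster stacks (shape ``(12, rows, cols)``),
and the outputs match.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely

from .grids import RasterLayer

__all__ = [
    "DailyClimateSeries",
    "MonthlyClimate",
    "GddResult",
    "gdd",
    "de_martonne",
    "de_martonne_monthly",
    "rainy_days",
    "windowed_variability",
    "bioclim",
    "BIOCLIM_NAMES",
    "landcover_percent",
    "monthly_climate_from_daily",
]

BIOCLIM_NAMES = tuple(f"BIO{i}" for i in range(1, 20))


@dataclass
class DailyClimateSeries:
    """Daily tmin/tmax/tmean (°C) and precipitation (mm/day) for one point.

    Backed by a date-indexed DataFrame; missing days are simply absent (or
    NaN).  Where tmean is not provided it defaults to (tmin + tmax)/2.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if not isinstance(df.index, pd.DatetimeIndex):
            df.index = pd.to_datetime(df.index)
        df = df.sort_index()
        if "tmean" not in df.columns and {"tmin", "tmax"} <= set(df.columns):
            df["tmean"] = (df["tmin"] + df["tmax"]) / 2.0
        if "prec" in df.columns and (df["prec"].dropna() < 0).any():
            raise ValueError("precipitation must be non-negative")
        self.data = df

    def window(self, period: tuple[_dt.date, _dt.date]) -> pd.DataFrame:
        start, end = period
        if end < start:
            raise ValueError("empty period")
        return self.data.loc[pd.Timestamp(start) : pd.Timestamp(end)]


class GddResult(NamedTuple):
    """Accumulated degree-days plus how many days entered / were skipped."""

    value: float
    n_days_used: int
    n_days_missing: int


def gdd(
    series: DailyClimateSeries,
    t_base: float,
    period: tuple[_dt.date, _dt.date],
) -> GddResult:
    """Growing degree days: sum of max(0, (tmax+tmin)/2 - t_base) over days.

    Days missing tmin or tmax are skipped and counted in
    ``n_days_missing``.
    """
    df = series.window(period)
    n_period = (period[1] - period[0]).days + 1
    if n_period <= 0:
        raise ValueError("empty period")
    ok = df[["tmin", "tmax"]].notna().all(axis=1) if len(df) else pd.Series(dtype=bool)
    used = df[ok] if len(df) else df
    daily_mean = (used["tmax"] + used["tmin"]) / 2.0 if len(used) else pd.Series(dtype=float)
    value = float(np.maximum(0.0, daily_mean - t_base).sum())
    return GddResult(value, int(len(used)), n_period - int(len(used)))


def de_martonne(annual_prec, annual_mean_temp):
    """De Martonne aridity index P/(T+10); undefined (NaN) at T <= -10 °C."""
    p = np.asarray(annual_prec, dtype=float)
    t = np.asarray(annual_mean_temp, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(t > -10.0, p / (t + 10.0), np.nan)
    return out if out.ndim else float(out)


def de_martonne_monthly(monthly_prec, monthly_mean_temp):
    """Monthly aridity variant 12*p/(t+10); NaN at t <= -10 °C."""
    p = np.asarray(monthly_prec, dtype=float)
    t = np.asarray(monthly_mean_temp, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(t > -10.0, 12.0 * p / (t + 10.0), np.nan)
    return out if out.ndim else float(out)


def rainy_days(
    series: DailyClimateSeries,
    threshold: float = 1.0,
    period: tuple[_dt.date, _dt.date] | None = None,
    *,
    strict: bool = False,
) -> int:
    """Days whose precipitation reaches ``threshold`` (inclusive by default)."""
    if period is None:
        if series.data.empty:
            raise ValueError("empty period")
        period = (series.data.index[0].date(), series.data.index[-1].date())
    df = series.window(period)
    prec = df["prec"].dropna()
    if strict:
        return int((prec > threshold).sum())
    return int((prec >= threshold).sum())


def windowed_variability(
    layers: Sequence[RasterLayer],
    *,
    min_n_sd: int = 2,
    min_n_kurtosis: int = 4,
) -> tuple[RasterLayer, RasterLayer]:
    """Per-pixel sample SD and excess kurtosis over a raster time window.

    SD uses the n-1 denominator and needs at least 2 valid observations;
    kurtosis is Fisher's excess (normal -> 0, population moments) and needs
    at least 4 valid observations and non-zero variance.  Pixels below the
    requirements are nodata.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("empty layer sequence")
    grid = layers[0].grid
    if any(l.grid != grid for l in layers):
        raise ValueError("all layers must share a GridSpec")

    stack = np.stack([l.values for l in layers])
    valid = np.stack([l.valid for l in layers])
    x = np.where(valid, stack, 0.0)
    n = valid.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x.sum(axis=0) / n
        dev = np.where(valid, stack - mean, 0.0)
        m2 = (dev**2).sum(axis=0) / n
        m4 = (dev**4).sum(axis=0) / n
        ss = (dev**2).sum(axis=0)
        sd = np.sqrt(ss / (n - 1))
        kurt = m4 / m2**2 - 3.0

    sd_mask = n < min_n_sd
    sd = np.where(sd_mask, np.nan, sd)
    kurt_mask = (n < min_n_kurtosis) | (m2 <= 1e-12)
    kurt = np.where(kurt_mask, np.nan, kurt)

    template = layers[0]
    return (
        template.replace(values=sd, nodata_mask=sd_mask, variable=f"{template.variable}_SD"),
        template.replace(values=kurt, nodata_mask=kurt_mask, variable=f"{template.variable}_KURT"),
    )


@dataclass
class MonthlyClimate:
    """Twelve months of tmin/tmax (°C) and precipitation totals (mm).

    Each field is an array whose leading axis has length 12 (January..
    December); trailing axes, if any, are spatial.  ``tmean`` defaults to
    (tmin + tmax)/2.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    tmean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        for name in ("tmin", "tmax", "prec"):
            arr = getattr(self, name)
            if arr.shape[0] != 12:
                raise ValueError(f"{name} must have 12 months, got {arr.shape[0]}")
        if self.tmean is None:
            self.tmean = (self.tmin + self.tmax) / 2.0
        else:
            self.tmean = np.asarray(self.tmean, dtype=float)

    def missing_months(self) -> list[int]:
        """1-based month numbers with any missing input."""
        bad = (
            ~np.isfinite(self.tmin)
            | ~np.isfinite(self.tmax)
            | ~np.isfinite(self.prec)
        )
        flat = bad.reshape(12, -1).any(axis=1)
        return [int(m) + 1 for m in np.nonzero(flat)[0]]


def _quarter_stats(monthly: MonthlyClimate) -> tuple[np.ndarray, np.ndarray]:
    """(quarter prec totals, quarter tmean means) for the 12 wrap-around
    3-month windows starting at each calendar month."""
    idx = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12
    qprec = monthly.prec[idx].sum(axis=1)
    qtemp = monthly.tmean[idx].mean(axis=1)
    return qprec, qtemp


def _take(arr: np.ndarray, which: np.ndarray) -> np.ndarray:
    """arr[which] along axis 0 with spatially varying ``which``."""
    return np.take_along_axis(arr, which[None, ...], axis=0)[0]


def bioclim(monthly: MonthlyClimate) -> dict[str, np.ndarray | float]:
    """The 19 standard bioclimatic variables from monthly climate.

    Quarters are all 12 consecutive 3-calendar-month windows including the
    wrap-around ones (Nov-Jan, Dec-Feb); ties pick the earliest quarter.
    BIO4 is 100x the sample SD of monthly mean temperature; BIO15 is 100x
    the sample SD of monthly precipitation over (mean + 1), the +1 guarding
    fully arid pixels.  BIO3 (isothermality) is NaN where BIO7 is zero.
    """
    missing = monthly.missing_months()
    if missing:
        raise ValueError(f"incomplete monthly climate; missing months: {missing}")

    tmin, tmax, prec, tmean = monthly.tmin, monthly.tmax, monthly.prec, monthly.tmean
    qprec, qtemp = _quarter_stats(monthly)

    out: dict[str, np.ndarray | float] = {}
    out["BIO1"] = tmean.mean(axis=0)
    out["BIO2"] = (tmax - tmin).mean(axis=0)
    out["BIO4"] = 100.0 * tmean.std(axis=0, ddof=1)
    out["BIO5"] = tmax.max(axis=0)
    out["BIO6"] = tmin.min(axis=0)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    with np.errstate(invalid="ignore", divide="ignore"):
        bio3 = np.where(out["BIO7"] != 0, 100.0 * out["BIO2"] / out["BIO7"], np.nan)
    out["BIO3"] = bio3

    wettest = np.argmax(qprec, axis=0)
    driest = np.argmin(qprec, axis=0)
    warmest = np.argmax(qtemp, axis=0)
    coldest = np.argmin(qtemp, axis=0)
    out["BIO8"] = _take(qtemp, wettest)
    out["BIO9"] = _take(qtemp, driest)
    out["BIO10"] = _take(qtemp, warmest)
    out["BIO11"] = _take(qtemp, coldest)

    out["BIO12"] = prec.sum(axis=0)
    out["BIO13"] = prec.max(axis=0)
    out["BIO14"] = prec.min(axis=0)
    out["BIO15"] = 100.0 * prec.std(axis=0, ddof=1) / (prec.mean(axis=0) + 1.0)
    out["BIO16"] = _take(qprec, wettest)
    out["BIO17"] = _take(qprec, driest)
    out["BIO18"] = _take(qprec, warmest)
    out["BIO19"] = _take(qprec, coldest)

    if tmean.ndim == 1:
        out = {k: float(v) for k, v in out.items()}
    return {name: out[name] for name in BIOCLIM_NAMES}


def monthly_climate_from_daily(
    series: DailyClimateSeries,
    year: int,
    *,
    max_missing_fraction: float = 0.2,
) -> MonthlyClimate:
    """Monthly means (temperature) and sums (precipitation) for one year.

    Months with more than ``max_missing_fraction`` of their days missing
    are set to NaN (and later rejected by :func:`bioclim`).
    """
    df = series.data.loc[f"{year}"]
    tmin = np.full(12, np.nan)
    tmax = np.full(12, np.nan)
    prec = np.full(12, np.nan)
    for m in range(1, 13):
        n_days = pd.Period(f"{year}-{m:02d}").days_in_month
        month = df[df.index.month == m] if len(df) else df
        for arr, col, how in ((tmin, "tmin", "mean"), (tmax, "tmax", "mean"), (prec, "prec", "sum")):
            vals = month[col].dropna() if col in month.columns else pd.Series(dtype=float)
            if len(vals) >= n_days * (1.0 - max_missing_fraction):
                arr[m - 1] = vals.mean() if how == "mean" else vals.sum()
    return MonthlyClimate(tmin, tmax, prec)


def landcover_percent(
    classes: RasterLayer,
    zones: RasterLayer | Mapping[object, "shapely.Geometry"],
) -> pd.DataFrame:
    """Per-zone percentage of each land-cover class.

    ``zones`` is either an integer zone raster on the same grid (nodata =
    outside any zone) or a mapping of zone id -> shapely polygon in the
    classes CRS (cell-center containment).  Percentages within a zone sum
    to 100 over the valid class cells; a zone with no valid cells yields an
    empty breakdown.
    """
    class_vals = np.round(classes.values).astype(np.int64)
    rows = []
    if isinstance(zones, RasterLayer):
        if zones.grid != classes.grid:
            raise ValueError("zone raster must share the classes GridSpec")
        zone_vals = np.round(zones.values).astype(np.int64)
        zone_ids = np.unique(zone_vals[zones.valid])
        for zid in zone_ids:
            inside = zones.valid & (zone_vals == zid) & classes.valid
            rows += _zone_rows(zid, class_vals[inside])
    else:
        x, y = classes.grid.cell_centers()
        for zid, geom in zones.items():
            inside = shapely.contains_xy(geom, x, y) & classes.valid
            rows += _zone_rows(zid, class_vals[inside])
    return pd.DataFrame(rows, columns=["zone", "class", "percent"])


def _zone_rows(zone_id, cells: np.ndarray) -> list[tuple]:
    if cells.size == 0:
        return []
    codes, counts = np.unique(cells, return_counts=True)
    total = counts.sum()
    return [
        (zone_id, int(code), 100.0 * count / total)
        for code, count in zip(codes, counts)
    ]
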