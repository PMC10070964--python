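"""Vegetation and water indices from surface-reflectance bands.

NDVI = (NIR - Red)/(NIR + Red) tracks green vegetation; EVI adds blue-band
and canopy-background corrections, EVI = G (NIR - Red)/(NIR + C1 Red -
C2 Blue + L) with the standard coefficients G=2.5, C1=6, C2=7.5, L=1; MNDWI
= (Green - SWIR)/(Green + SWIR) highlights open water.  Inputs are
dimensionless reflectances nominally in [0, 1]; integer-scaled products
(x10,000) should be divided by their declared scale on read.

A 16-day maximum-value composite series is aligned to the 8-day thermal
cadence by inserting the pairwise mean of consecutive images at the
midpoint date, keeping the originals.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import RasterLayer

__all__ = [
    "BandSet",
    "ndvi",
    "evi",
    "mndwi",
    "normalized_difference",
    "pairwise_temporal_average",
    "EVI_COEFFICIENTS",
]

#: Standard EVI coefficients (gain, canopy/aerosol terms, soil adjustment).
EVI_COEFFICIENTS = {"G": 2.5, "C1": 6.0, "C2": 7.5, "L": 1.0}

_DENOM_EPS = 1e-12


@dataclass
class BandSet:
    """Co-registered reflectance bands of one scene (shared grid and date)."""

    date: _dt.date | None = None
    blue: RasterLayer | None = None
    green: RasterLayer | None = None
    red: RasterLayer | None = None
    nir: RasterLayer | None = None
    swir: RasterLayer | None = None

    def __post_init__(self) -> None:
        grids = {b.grid for b in self._present()}
        if len(grids) > 1:
            raise ValueError("all bands must share a GridSpec")
        for b in self._present():
            if np.any(b.values[b.valid] < 0):
                raise ValueError("reflectances must be non-negative where valid")

    def _present(self):
        return [
            b
            for b in (self.blue, self.green, self.red, self.nir, self.swir)
            if b is not None
        ]

    def require(self, *names: str) -> list[RasterLayer]:
        got = []
        for name in names:
            band = getattr(self, name)
            if band is None:
                raise ValueError(f"missing band {name!r}")
            got.append(band)
        return got


def normalized_difference(
    plus: RasterLayer, minus: RasterLayer, variable: str
) -> RasterLayer:
    """(plus - minus)/(plus + minus), clipped to [-1, 1]; 0/0 is nodata."""
    if plus.grid != minus.grid:
        raise ValueError("bands must share a GridSpec")
    denom = plus.values + minus.values
    bad = plus.nodata_mask | minus.nodata_mask | (np.abs(denom) < _DENOM_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (plus.values - minus.values) / denom
    ratio = np.clip(ratio, -1.0, 1.0)
    ratio = np.where(bad, np.nan, ratio)
    return plus.replace(values=ratio, nodata_mask=bad, variable=variable)


def ndvi(bands: BandSet) -> RasterLayer:
    """Normalized Difference Vegetation Index from Red and NIR."""
    nir, red = bands.require("nir", "red")
    out = normalized_difference(nir, red, "NDVI")
    return out.replace(timestamp=bands.date or out.timestamp)


def mndwi(bands: BandSet) -> RasterLayer:
    """Modified Normalized Difference Water Index from Green and SWIR."""
    green, swir = bands.require("green", "swir")
    out = normalized_difference(green, swir, "MNDWI")
    return out.replace(timestamp=bands.date or out.timestamp)


def evi(bands: BandSet, coefficients: dict[str, float] | None = None) -> RasterLayer:
    """Enhanced Vegetation Index from Red, NIR and Blue.

    Unclipped (unlike NDVI/MNDWI); near-zero denominators become nodata.
    """
    nir, red, blue = bands.require("nir", "red", "blue")
    c = dict(EVI_COEFFICIENTS)
    if coefficients:
        c.update(coefficients)
    denom = nir.values + c["C1"] * red.values - c["C2"] * blue.values + c["L"]
    bad = (
        nir.nodata_mask
        | red.nodata_mask
        | blue.nodata_mask
        | (np.abs(denom) < 1e-6)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        value = c["G"] * (nir.values - red.values) / denom
    value = np.where(bad, np.nan, value)
    return nir.replace(
        values=value, nodata_mask=bad, variable="EVI",
        timestamp=bands.date or nir.timestamp,
    )


def _nodata_aware_mean(a: RasterLayer, b: RasterLayer) -> RasterLayer:
    both = a.valid & b.valid
    only_a = a.valid & ~b.valid
    only_b = b.valid & ~a.valid
    values = np.full(a.grid.shape, np.nan)
    values[both] = 0.5 * (a.values[both] + b.values[both])
    values[only_a] = a.values[only_a]
    values[only_b] = b.values[only_b]
    mask = ~(both | only_a | only_b)
    return a.replace(values=values, nodata_mask=mask)


def pairwise_temporal_average(
    series: Sequence[RasterLayer],
) -> list[RasterLayer]:
    """Interleave a 16-day series with pairwise-mean midpoints (8-day cadence).

    For consecutive layers at t and t+16 an averaged layer timestamped t+8
    is inserted; originals are preserved.  The per-pixel mean is
    nodata-aware: a pixel valid in only one of the pair takes that value.
    Fewer than two layers are returned unchanged.
    """
    series = list(series)
    if len(series) < 2:
        return series
    dates = [layer.timestamp for layer in series]
    if any(d is None for d in dates):
        raise ValueError("all layers need a timestamp")
    if any(d2 <= d1 for d1, d2 in zip(dates, dates[1:])):
        raise ValueError("timestamps must be strictly increasing")

    out: list[RasterLayer] = []
    for first, second in zip(series, series[1:]):
        out.append(first)
        gap = (second.timestamp - first.timestamp).days
        mid = _nodata_aware_mean(first, second)
        out.append(mid.replace(timestamp=first.timestamp + _dt.timedelta(days=gap // 2)))
    out.append(series[-1])
    return out
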