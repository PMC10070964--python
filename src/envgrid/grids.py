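"""Geographical levels, master-grid alignment and resampling.

Every raster product the pipelines touch lives on one of three geographical
levels:

* ``LOCAL`` — north-eastern Italy (Triveneto), EPSG:32632 (UTM32N), the
  finest grids (200 m .. 1 km);
* ``COUNTRY`` — Italy, EPSG:32632, 1 km and coarser;
* ``CONTINENTAL`` — western Europe, EPSG:4326, degree-based grids.

Within the two UTM levels all cell sizes are integer multiples or integer
submultiples of 1 km, and every layer is snapped to a single master lattice
so that cells of different products coincide.  The master-grid origins are
fixed round-kilometer corners declared below; any fixed round-km corner
satisfies the multiples/submultiples rule.

Conventions: the grid origin is the *top-left corner of the top-left cell*;
row index increases southward; sampling is cell-center registered; extents
are half-open ``[min, max)``.  Missing data are carried as an explicit
boolean mask (``True`` = nodata), serialized as a sentinel value on disk.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from . import crs as _crs

__all__ = [
    "GridSpec",
    "Level",
    "RasterLayer",
    "LEVELS",
    "master_grid",
    "snap_resolution",
    "align_to_master",
    "block_aggregate",
    "reproject",
    "AlignmentError",
]

KM = 1000.0


class AlignmentError(ValueError):
    """Raised when a layer cannot be brought onto the requested grid."""


@dataclass(frozen=True)
class GridSpec:
    """A georeferenced regular grid.

    Parameters
    ----------
    crs_code:
        CRS identifier; ``EPSG:32632`` for the local/country levels,
        ``EPSG:4326`` for the continental level.
    origin_x, origin_y:
        Coordinates of the top-left corner of the top-left cell, in CRS
        units (meters or degrees).
    cell_size:
        Cell edge length in CRS units; must be positive.
    n_rows, n_cols:
        Grid shape; positive integers.
    """

    crs_code: str
    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y), half-open on the max side."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y coordinates of every cell center (2-D)."""
        cols = np.arange(self.n_cols) + 0.5
        rows = np.arange(self.n_rows) + 0.5
        x = self.origin_x + cols * self.cell_size
        y = self.origin_y - rows * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) array indices of points, center-registered."""
        col = (np.asarray(x, float) - self.origin_x) / self.cell_size - 0.5
        row = (self.origin_y - np.asarray(y, float)) / self.cell_size - 0.5
        return row, col

    def same_lattice(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        """Whether both grids share CRS, cell size and lattice phase."""
        if self.crs_code != other.crs_code:
            return False
        if not math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9):
            return False
        dx = (self.origin_x - other.origin_x) / self.cell_size
        dy = (self.origin_y - other.origin_y) / self.cell_size
        return (
            abs(dx - round(dx)) < tol
            and abs(dy - round(dy)) < tol
        )


@dataclass(frozen=True)
class Level:
    """One of the three geographical levels with its CRS and extent."""

    code: str
    crs_code: str
    extent: tuple[float, float, float, float]  # (min_x, min_y, max_x, max_y)


#: Declared level extents.  The local extent nests inside the country
#: extent (both UTM32N); the continental level uses WGS84 and need not nest.
LEVELS: dict[str, Level] = {
    "LOCAL": Level("LOCAL", _crs.UTM32N, (600_000.0, 5_050_000.0, 860_000.0, 5_250_000.0)),
    "COUNTRY": Level("COUNTRY", _crs.UTM32N, (200_000.0, 3_900_000.0, 1_350_000.0, 5_350_000.0)),
    "CONTINENTAL": Level("CONTINENTAL", _crs.WGS84, (-11.0, 34.0, 32.0, 61.0)),
}

#: Fixed master-grid top-left origins (round-kilometer corners for the UTM
#: levels, round degrees for the continental level).
MASTER_ORIGINS: dict[str, tuple[float, float]] = {
    "LOCAL": (600_000.0, 5_250_000.0),
    "COUNTRY": (200_000.0, 5_350_000.0),
    "CONTINENTAL": (-11.0, 61.0),
}


def master_grid(level: str, cell_size: float) -> GridSpec:
    """The master GridSpec covering a level's extent at ``cell_size``."""
    lv = LEVELS[level]
    ox, oy = MASTER_ORIGINS[level]
    xmin, ymin, xmax, ymax = lv.extent
    n_cols = int(math.ceil((xmax - ox) / cell_size))
    n_rows = int(math.ceil((oy - ymin) / cell_size))
    return GridSpec(lv.crs_code, ox, oy, cell_size, n_rows, n_cols)


@dataclass
class RasterLayer:
    """A 2-D value field bound to a :class:`GridSpec` with nodata semantics.

    ``values`` holds finite numbers wherever ``nodata_mask`` is False; the
    content of masked cells is unspecified.
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    variable: str = ""
    level: str = ""
    timestamp: _dt.date | None = None
    hour_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    # -- convenience -------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def filled(self, fill=np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def replace(self, **kwargs) -> "RasterLayer":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Resolution snapping


def snap_resolution(native_res: float, product=None, *, units: str = "m") -> float:
    """Target cell size in meters for a native product resolution.

    If ``product`` (a registry entry, see :mod:`envgrid.catalog`) declares an
    explicit target cell size, that wins — the registry carries the published
    per-product resolutions (27 km for the 0.25-degree gridded-station
    product, 10 km for the satellite precipitation product).  Otherwise the
    native resolution is rounded half-up to the nearest whole kilometer.

    ``units`` is ``"m"`` or ``"deg"``; degree inputs without a registry
    override are converted at 111.32 km/degree before rounding.
    """
    if native_res <= 0:
        raise ValueError("native_res must be positive")
    if product is not None:
        target = getattr(product, "target_cell_size", None)
        if target is not None:
            return float(target)
    if units == "deg":
        km = native_res * 111.32
    elif units == "m":
        km = native_res / KM
    else:
        raise ValueError(f"unknown units {units!r}")
    return max(1.0, math.floor(km + 0.5)) * KM


def _snap_cell_size(native: float, master_cell: float) -> float:
    """Closest integer multiple or submultiple of ``master_cell``."""
    if native >= master_cell:
        k = native / master_cell
        candidates = {max(1, math.floor(k)), math.ceil(k)}
        return min(
            (master_cell * c for c in candidates), key=lambda v: abs(v - native)
        )
    k = master_cell / native
    candidates = {max(1, math.floor(k)), math.ceil(k)}
    return min(
        (master_cell / c for c in candidates), key=lambda v: abs(v - native)
    )


# ---------------------------------------------------------------------------
# Sampling engine shared by align_to_master and reproject


def _sample_nearest(layer: RasterLayer, row: np.ndarray, col: np.ndarray):
    r = np.round(row).astype(int)
    c = np.round(col).astype(int)
    inside = (r >= 0) & (r < layer.grid.n_rows) & (c >= 0) & (c < layer.grid.n_cols)
    rc = np.clip(r, 0, layer.grid.n_rows - 1)
    cc = np.clip(c, 0, layer.grid.n_cols - 1)
    values = layer.values[rc, cc]
    mask = ~inside | layer.nodata_mask[rc, cc]
    return values, mask


def _sample_bilinear(layer: RasterLayer, row: np.ndarray, col: np.ndarray):
    # Nodata-aware bilinear: interpolate value*weight and weight separately,
    # so constants are preserved and nodata does not bleed numeric garbage.
    w = layer.valid.astype(float)
    v = np.where(layer.valid, layer.values, 0.0)
    coords = np.stack([row.ravel(), col.ravel()])
    num = ndimage.map_coordinates(v, coords, order=1, mode="constant", cval=0.0)
    den = ndimage.map_coordinates(w, coords, order=1, mode="constant", cval=0.0)
    inside = (
        (row.ravel() >= -0.5)
        & (row.ravel() <= layer.grid.n_rows - 0.5)
        & (col.ravel() >= -0.5)
        & (col.ravel() <= layer.grid.n_cols - 0.5)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / den
    mask = (den < 0.5) | ~inside
    values = np.where(mask, np.nan, values)
    return values.reshape(row.shape), mask.reshape(row.shape)


def _sample(layer: RasterLayer, x: np.ndarray, y: np.ndarray, method: str):
    row, col = layer.grid.index_of(x, y)
    if method == "nearest":
        return _sample_nearest(layer, row, col)
    if method == "bilinear":
        return _sample_bilinear(layer, row, col)
    raise ValueError(f"unknown sampling method {method!r}")


def _block_mean_onto(layer: RasterLayer, target: GridSpec):
    """Mean of valid input cells whose centers fall in each target cell."""
    x, y = layer.grid.cell_centers()
    col = np.floor((x - target.origin_x) / target.cell_size).astype(int)
    row = np.floor((target.origin_y - y) / target.cell_size).astype(int)
    ok = (
        layer.valid
        & (row >= 0)
        & (row < target.n_rows)
        & (col >= 0)
        & (col < target.n_cols)
    )
    flat = row[ok] * target.n_cols + col[ok]
    sums = np.bincount(flat, weights=layer.values[ok], minlength=target.n_rows * target.n_cols)
    counts = np.bincount(flat, minlength=target.n_rows * target.n_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    values = means.reshape(target.shape)
    mask = counts.reshape(target.shape) == 0
    values = np.where(mask, np.nan, values)
    return values, mask


def align_to_master(
    layer: RasterLayer,
    master: GridSpec,
    method: str = "nearest",
    cell_size: float | None = None,
) -> RasterLayer:
    """Snap a layer onto the master lattice.

    The output grid's cell size is the integer multiple or submultiple of
    the master cell size closest to the layer's native resolution (or an
    explicit ``cell_size``), and its origin sits on the master lattice at
    the coarser of the target and master spacings, so cell boundaries of
    aligned layers coincide across products.  ``method`` is one of
    ``nearest``, ``bilinear`` or ``block-mean``; nodata propagates (a
    block mean over all-nodata input is nodata).
    """
    if layer.grid.crs_code != master.crs_code:
        raise AlignmentError(
            f"layer CRS {layer.grid.crs_code} != master CRS {master.crs_code}; "
            "reproject first"
        )
    if cell_size is None:
        cell = _snap_cell_size(layer.grid.cell_size, master.cell_size)
    else:
        cell = _snap_cell_size(cell_size, master.cell_size)

    # Snap the layer's bounding box outward onto the master-anchored
    # lattice, using the coarser spacing so a fine grid's origin also sits
    # on the coarse master boundaries.
    spacing = max(cell, master.cell_size)
    ox = master.origin_x + math.floor(
        (layer.grid.origin_x - master.origin_x) / spacing + 1e-9
    ) * spacing
    oy = master.origin_y - math.floor(
        (master.origin_y - layer.grid.origin_y) / spacing + 1e-9
    ) * spacing
    xmin, ymin, xmax, ymax = layer.grid.bounds
    n_cols = max(1, int(math.ceil((xmax - ox) / cell - 1e-9)))
    n_rows = max(1, int(math.ceil((oy - ymin) / cell - 1e-9)))
    target = GridSpec(master.crs_code, ox, oy, cell, n_rows, n_cols)

    if target.same_lattice(layer.grid) and target == layer.grid:
        return layer.replace(grid=target, values=layer.values.copy(),
                             nodata_mask=layer.nodata_mask.copy())

    if method == "block-mean":
        values, mask = _block_mean_onto(layer, target)
    else:
        x, y = target.cell_centers()
        values, mask = _sample(layer, x, y, method)
    return layer.replace(grid=target, values=values, nodata_mask=mask)


def block_aggregate(layer: RasterLayer, factor: int) -> RasterLayer:
    """Aggregate ``factor`` x ``factor`` blocks by their valid-cell mean.

    Used e.g. to bring 10 m reflectance-index rasters to the 200 m local
    grid (factor 20).  Dimensions not divisible by ``factor`` are padded
    with nodata; blocks with no valid cell are nodata.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return layer.replace(values=layer.values.copy(),
                             nodata_mask=layer.nodata_mask.copy())

    nr = int(math.ceil(layer.grid.n_rows / factor)) * factor
    nc = int(math.ceil(layer.grid.n_cols / factor)) * factor
    v = np.full((nr, nc), np.nan)
    m = np.ones((nr, nc), dtype=bool)
    v[: layer.grid.n_rows, : layer.grid.n_cols] = layer.values
    m[: layer.grid.n_rows, : layer.grid.n_cols] = layer.nodata_mask

    valid = (~m).reshape(nr // factor, factor, nc // factor, factor)
    vals = np.where(~m, v, 0.0).reshape(nr // factor, factor, nc // factor, factor)
    counts = valid.sum(axis=(1, 3))
    sums = vals.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    mask = counts == 0
    means = np.where(mask, np.nan, means)

    grid = GridSpec(
        layer.grid.crs_code,
        layer.grid.origin_x,
        layer.grid.origin_y,
        layer.grid.cell_size * factor,
        nr // factor,
        nc // factor,
    )
    return layer.replace(grid=grid, values=means, nodata_mask=mask)


def reproject(
    layer: RasterLayer,
    target_crs: str,
    target_grid: GridSpec,
    *,
    categorical: bool = False,
) -> RasterLayer:
    """Resample a layer onto a grid in another (or the same) CRS.

    Nearest-neighbour is used for categorical variables, bilinear for
    continuous ones.  Target cell centers are transformed into the source
    CRS and the source layer is sampled there.
    """
    if target_grid.crs_code != target_crs:
        raise ValueError("target_grid CRS must equal target_crs")
    if target_crs == layer.grid.crs_code and target_grid == layer.grid:
        return layer.replace(values=layer.values.copy(),
                             nodata_mask=layer.nodata_mask.copy())
    x, y = target_grid.cell_centers()
    sx, sy = _crs.transform(target_crs, layer.grid.crs_code, x, y)
    method = "nearest" if categorical else "bilinear"
    values, mask = _sample(layer, sx, sy, method)
    return layer.replace(grid=target_grid, values=values, nodata_mask=mask)
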