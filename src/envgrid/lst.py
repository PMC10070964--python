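"""Land-surface-temperature cleaning, reconstruction and compositing.

Two product chains are implemented:

* country/continental: quality-masked acquisitions averaged into 8-day
  composites at 1 km (windows restart at day-of-year 1 each year, so the
  last window of a year may be short);
* local: the four daily acquisitions (two satellites x day/night overpass)
  are scaled to degrees Celsius, cleaned with the QC band, outlier-filtered
  twice — against the scene's own value distribution (median +/- k*MAD) and
  against the altitudinal lapse regression of temperature on elevation —
  and finally reconstructed to a gap-free 200 m field: each missing pixel
  receives the lapse-model prediction at its elevation plus a smooth
  residual surface interpolated from the surviving observations.

The lapse regression is refitted per scene (per date x overpass); pooling
across scenes would blur the strong diurnal cycle of the gradient.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator

from .grids import RasterLayer, reproject
from .qc import QCPolicy, apply_qc_mask

__all__ = [
    "LstAcquisition",
    "LapseModel",
    "scale_lst",
    "filter_distribution",
    "fit_lapse_model",
    "filter_lapse_outliers",
    "reconstruct_gaps",
    "composite_8day",
    "eight_day_windows",
    "process_local_day",
    "OVERPASSES",
]

#: The four daily overpass classes (satellite x day/night), used as the
#: hour surrogate in filenames and catalog queries.
OVERPASSES = ("TERRA-DAY", "TERRA-NIGHT", "AQUA-DAY", "AQUA-NIGHT")

#: Thermal-product scaling convention: DN * 0.02 K, converted to Celsius.
LST_SCALE = 0.02
KELVIN_OFFSET = 273.15

_MIN_VALID_DISTRIBUTION = 25
_MIN_VALID_FIT = 30
_MAD_EPS = 1e-6
_MAX_RBF_ANCHORS = 1200


@dataclass(frozen=True)
class LstAcquisition:
    """One satellite overpass: a °C layer tagged satellite/overpass/date."""

    layer: RasterLayer
    satellite: str  # TERRA or AQUA
    overpass: str  # DAY or NIGHT
    date: _dt.date

    @property
    def hour_tag(self) -> str:
        return f"{self.satellite}-{self.overpass}"


@dataclass(frozen=True)
class LapseModel:
    """OLS fit of LST on elevation: lst = intercept + slope * elev."""

    intercept: float
    slope: float
    residual_sd: float
    n_fit: int

    def predict(self, elevation: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(elevation, float)


def scale_lst(dn_layer: RasterLayer) -> RasterLayer:
    """Digital numbers -> °C (value * 0.02 - 273.15); DN 0 is fill."""
    dn = dn_layer.values
    if np.any(dn[~dn_layer.nodata_mask] < 0):
        raise ValueError("digital numbers must be non-negative")
    mask = dn_layer.nodata_mask | (dn == 0)
    celsius = dn * LST_SCALE - KELVIN_OFFSET
    return dn_layer.replace(values=celsius, nodata_mask=mask, variable="LST")


def filter_distribution(
    layer: RasterLayer, k_mad: float = 5.0, min_valid: int = _MIN_VALID_DISTRIBUTION
) -> RasterLayer:
    """Mask pixels farther than ``k_mad`` robust deviations from the median.

    The scale is the median absolute deviation, floored at a small epsilon
    so constant fields pass through unchanged.  With fewer than
    ``min_valid`` valid pixels the layer is returned unchanged.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    vals = layer.valid_values()
    if vals.size < min_valid:
        return layer.replace(values=layer.values.copy(),
                             nodata_mask=layer.nodata_mask.copy())
    med = np.median(vals)
    mad = max(np.median(np.abs(vals - med)), _MAD_EPS)
    out = np.abs(layer.values - med) > k_mad * mad
    return layer.replace(
        values=layer.values.copy(), nodata_mask=layer.nodata_mask | out
    )


def fit_lapse_model(
    layer: RasterLayer, dem: RasterLayer, min_valid: int = _MIN_VALID_FIT
) -> LapseModel:
    """Ordinary least squares of LST on elevation over jointly valid pixels."""
    if layer.grid != dem.grid:
        raise ValueError("layer and DEM must share a GridSpec")
    ok = layer.valid & dem.valid
    n = int(ok.sum())
    if n < min_valid:
        raise ValueError(f"only {n} jointly valid pixels (need {min_valid})")
    elev = dem.values[ok]
    lst = layer.values[ok]
    if np.ptp(elev) == 0:
        raise ValueError("degenerate (constant) elevation: lapse fit undefined")
    slope, intercept = np.polyfit(elev, lst, 1)
    resid = lst - (intercept + slope * elev)
    dof = max(n - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return LapseModel(float(intercept), float(slope), residual_sd, n)


def filter_lapse_outliers(
    layer: RasterLayer, dem: RasterLayer, model: LapseModel, k_sigma: float = 3.0
) -> RasterLayer:
    """Mask pixels departing more than ``k_sigma`` residual SDs from the
    lapse prediction at their elevation.

    With zero residual SD only exact matches survive.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    if layer.grid != dem.grid:
        raise ValueError("layer and DEM must share a GridSpec")
    predicted = model.predict(dem.values)
    threshold = k_sigma * model.residual_sd
    out = np.abs(layer.values - predicted) > threshold
    out |= dem.nodata_mask
    return layer.replace(
        values=layer.values.copy(), nodata_mask=layer.nodata_mask | out
    )


def _interpolate_residual_surface(
    grid_shape: tuple[int, int],
    anchor_rows: np.ndarray,
    anchor_cols: np.ndarray,
    anchor_values: np.ndarray,
    smoothing: float,
) -> np.ndarray:
    """Smooth residual surface through scattered anchors (thin-plate spline).

    Anchors beyond a cap are thinned by even striding to keep the dense
    spline solve tractable; the surface remains exact at retained anchors
    when smoothing is zero.
    """
    n = anchor_values.size
    if n > _MAX_RBF_ANCHORS:
        idx = np.linspace(0, n - 1, _MAX_RBF_ANCHORS).astype(int)
        anchor_rows, anchor_cols = anchor_rows[idx], anchor_cols[idx]
        anchor_values = anchor_values[idx]
    pts = np.column_stack([anchor_rows, anchor_cols]).astype(float)
    rbf = RBFInterpolator(
        pts, anchor_values, kernel="thin_plate_spline", smoothing=smoothing
    )
    rr, cc = np.meshgrid(
        np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij"
    )
    query = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    return rbf(query).reshape(grid_shape)


def reconstruct_gaps(
    layer: RasterLayer,
    dem: RasterLayer,
    model: LapseModel | None = None,
    *,
    smoothing: float = 0.0,
) -> RasterLayer:
    """Fill every nodata pixel from the lapse model plus a residual surface.

    The target grid is the DEM grid (the fine 200 m grid); a coarser
    observed layer is first assigned to the fine cells by nearest
    neighbour.  Observed pixels keep their values; gaps receive
    ``intercept + slope*elev`` plus a thin-plate residual surface anchored
    at the observed pixels, so the output has zero nodata cells.
    """
    if layer.grid != dem.grid:
        layer = reproject(layer, dem.grid.crs_code, dem.grid, categorical=True)
    if model is None:
        model = fit_lapse_model(layer, dem)
    ok = layer.valid & dem.valid
    if not ok.any():
        raise ValueError("no valid pixels to anchor the reconstruction")
    if not layer.nodata_mask.any():
        return layer.replace(values=layer.values.copy(),
                             nodata_mask=np.zeros(layer.grid.shape, bool))

    predicted = model.predict(dem.values)
    residuals = layer.values - predicted
    rows, cols = np.nonzero(ok)
    if np.max(np.abs(residuals[ok])) < 1e-12:
        surface = np.zeros(layer.grid.shape)
    else:
        surface = _interpolate_residual_surface(
            layer.grid.shape, rows, cols, residuals[ok], smoothing
        )
    filled = np.where(layer.nodata_mask, predicted + surface, layer.values)
    return layer.replace(
        values=filled, nodata_mask=np.zeros(layer.grid.shape, dtype=bool)
    )


# ---------------------------------------------------------------------------
# Temporal compositing


def eight_day_windows(year: int) -> list[tuple[_dt.date, _dt.date]]:
    """The 8-day composite windows of a year (starts at DOY 1, 9, 17, ...).

    Returned as half-open [start, end) date pairs; the last window is
    truncated at 1 January of the next year, so a non-leap year has 46
    windows (45 full plus one 5-day tail).
    """
    start = _dt.date(year, 1, 1)
    year_end = _dt.date(year + 1, 1, 1)
    windows = []
    while start < year_end:
        end = min(start + _dt.timedelta(days=8), year_end)
        windows.append((start, end))
        start = end
    return windows


def composite_8day(
    acquisitions: Sequence[LstAcquisition], window_start_doy: int
) -> RasterLayer:
    """Per-pixel mean of valid observations inside one 8-day window."""
    if not acquisitions:
        raise ValueError("empty window: no acquisitions to composite")
    year = acquisitions[0].date.year
    w_start = _dt.date(year, 1, 1) + _dt.timedelta(days=window_start_doy - 1)
    w_end = min(w_start + _dt.timedelta(days=8), _dt.date(year + 1, 1, 1))
    grid = acquisitions[0].layer.grid
    for acq in acquisitions:
        if acq.layer.grid != grid:
            raise ValueError("all acquisitions must share a GridSpec")
        if not (w_start <= acq.date < w_end):
            raise ValueError(f"acquisition {acq.date} outside window {w_start}..{w_end}")

    stack = np.stack([a.layer.values for a in acquisitions])
    valid = np.stack([a.layer.valid for a in acquisitions])
    counts = valid.sum(axis=0)
    sums = np.where(valid, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mask = counts == 0
    mean = np.where(mask, np.nan, mean)
    return acquisitions[0].layer.replace(
        values=mean, nodata_mask=mask, timestamp=w_start, hour_tag=None
    )


def process_local_day(
    acquisitions: Iterable[LstAcquisition],
    qc_layers: dict[str, RasterLayer],
    dem: RasterLayer,
    *,
    policy: QCPolicy = QCPolicy(),
    k_mad: float = 5.0,
    k_sigma: float = 3.0,
    smoothing: float = 0.0,
) -> list[RasterLayer]:
    """The full local chain for one day: QC -> outlier filters -> gap fill.

    ``qc_layers`` maps the overpass hour tag (e.g. ``TERRA-DAY``) to its QC
    raster.  Emits one gap-free layer per overpass, tagged with the
    satellite/overpass hour surrogate.
    """
    out = []
    for acq in acquisitions:
        layer = acq.layer
        qc = qc_layers.get(acq.hour_tag)
        if qc is not None:
            layer = apply_qc_mask(layer, qc, policy)
        layer = filter_distribution(layer, k_mad=k_mad)
        model = fit_lapse_model(layer, dem)
        layer = filter_lapse_outliers(layer, dem, model, k_sigma=k_sigma)
        model = fit_lapse_model(layer, dem)
        layer = reconstruct_gaps(layer, dem, model, smoothing=smoothing)
        out.append(
            layer.replace(
                variable="LST", timestamp=acq.date, hour_tag=acq.hour_tag
            )
        )
    return out
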