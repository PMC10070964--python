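"""GeoTIFF and NetCDF serialization for :class:`~envgrid.grids.RasterLayer`.

GeoTIFF files are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) so the output
opens correctly in GIS software.  Integer rasters round-trip bit-exactly;
nodata is encoded as a declared sentinel value and restored to an explicit
mask on read.  NetCDF output uses the classic (NetCDF-3) format with named
``y``/``x`` coordinate variables holding cell-center coordinates.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from . import crs as _crs
from .grids import GridSpec, RasterLayer

__all__ = ["write_geotiff", "read_geotiff", "write_netcdf", "read_netcdf"]

_DEFAULT_NODATA_FLOAT = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


def _geokeys_for(crs_code: str) -> list[int]:
    epsg = int(crs_code.split(":")[1])
    if crs_code == _crs.WGS84:
        keys = [(_KEY_MODEL_TYPE, 2), (_KEY_RASTER_TYPE, 1), (_KEY_GEOGRAPHIC_CS, epsg)]
    else:
        keys = [(_KEY_MODEL_TYPE, 1), (_KEY_RASTER_TYPE, 1), (_KEY_PROJECTED_CS, epsg)]
    directory = [1, 1, 0, len(keys)]
    for key_id, value in keys:
        directory += [key_id, 0, 1, value]
    return directory


def _crs_from_geokeys(directory) -> str:
    values = list(directory)
    n = values[3]
    for i in range(n):
        key_id, _, _, value = values[4 + 4 * i : 8 + 4 * i]
        if key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
            return f"EPSG:{value}"
    raise ValueError("GeoTIFF carries no recognised CRS geokey")


def write_geotiff(
    layer: RasterLayer,
    path: str | Path,
    *,
    dtype: np.dtype | str | None = None,
    nodata: float | None = None,
) -> Path:
    """Write a layer as a single-band GeoTIFF.

    ``dtype`` defaults to the values' dtype (float64 for science layers;
    pass an integer dtype for QC/class rasters).  ``nodata`` defaults to
    -9999 for float output and to the dtype minimum (signed) or maximum
    (unsigned) for integer output.
    """
    path = Path(path)
    dtype = np.dtype(dtype) if dtype is not None else layer.values.dtype
    if nodata is None:
        if np.issubdtype(dtype, np.signedinteger):
            nodata = float(np.iinfo(dtype).min)
        elif np.issubdtype(dtype, np.unsignedinteger):
            nodata = float(np.iinfo(dtype).max)
        else:
            nodata = _DEFAULT_NODATA_FLOAT
    data = layer.values.copy()
    data[layer.nodata_mask] = nodata
    data = data.astype(dtype)

    g = layer.grid
    geokeys = _geokeys_for(g.crs_code)
    if np.issubdtype(dtype, np.integer):
        nodata_text = repr(int(nodata)).encode() + b"\x00"
    else:
        nodata_text = repr(nodata).encode() + b"\x00"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys, True),
        (_TAG_GDAL_NODATA, "s", len(nodata_text), nodata_text, True),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    return path


def read_geotiff(
    path: str | Path,
    *,
    variable: str = "",
    level: str = "",
    timestamp: _dt.date | None = None,
    hour_tag: str | None = None,
) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_TIEPOINT].value
        crs_code = _crs_from_geokeys(page.tags[_TAG_GEO_KEYS].value)
        nodata = None
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(str(page.tags[_TAG_GDAL_NODATA].value).strip("\x00"))

    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    n_rows, n_cols = data.shape
    grid = GridSpec(crs_code, float(tiepoint[3]), float(tiepoint[4]),
                    float(scale[0]), n_rows, n_cols)
    mask = np.zeros(data.shape, dtype=bool) if nodata is None else data == nodata
    return RasterLayer(
        grid=grid,
        values=data.astype(float),
        nodata_mask=mask,
        variable=variable,
        level=level,
        timestamp=timestamp,
        hour_tag=hour_tag,
    )


def read_geotiff_raw(path: str | Path) -> np.ndarray:
    """The raw on-disk band, untouched (for bit-exactness checks)."""
    with tifffile.TiffFile(str(path)) as tif:
        return tif.pages[0].asarray()


def write_netcdf(layer: RasterLayer, path: str | Path, name: str | None = None) -> Path:
    """Write a layer as a classic NetCDF file with y/x center coordinates."""
    path = Path(path)
    name = name or layer.variable or "value"
    x, y = layer.grid.cell_centers()
    da = xr.DataArray(
        layer.filled(np.nan),
        dims=("y", "x"),
        coords={"y": y[:, 0], "x": x[0, :]},
        name=name,
        attrs={
            "crs_code": layer.grid.crs_code,
            "cell_size": layer.grid.cell_size,
            "origin_x": layer.grid.origin_x,
            "origin_y": layer.grid.origin_y,
        },
    )
    if layer.timestamp is not None:
        da.attrs["timestamp"] = layer.timestamp.isoformat()
    if layer.level:
        da.attrs["level"] = layer.level
    da.to_dataset().to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read a layer written by :func:`write_netcdf`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if name is None:
            name = next(iter(ds.data_vars))
        da = ds[name].load()
    values = np.asarray(da.values, dtype=float)
    grid = GridSpec(
        da.attrs["crs_code"],
        float(da.attrs["origin_x"]),
        float(da.attrs["origin_y"]),
        float(da.attrs["cell_size"]),
        values.shape[0],
        values.shape[1],
    )
    ts = None
    if "timestamp" in da.attrs:
        ts = _dt.date.fromisoformat(str(da.attrs["timestamp"]))
    return RasterLayer(
        grid=grid,
        values=values,
        nodata_mask=~np.isfinite(values),
        variable=str(name),
        level=str(da.attrs.get("level", "")),
        timestamp=ts,
    )
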