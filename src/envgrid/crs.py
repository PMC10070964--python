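"""Coordinate transforms between the two CRSs the pipelines use.

Only two reference systems appear in the data model: projected UTM zone 32N
(EPSG:32632) for the local and country levels, and geographic WGS84
(EPSG:4326) for the continental level.  The conversion between them is the
standard transverse-Mercator forward/inverse series on the WGS84 ellipsoid
(Snyder, *Map Projections — A Working Manual*, USGS PP 1395, eqs. 8-9..8-25),
accurate to well under a centimeter over the zone.

All functions are vectorized over numpy arrays.
"""

from __future__ import annotations

import numpy as np

UTM32N = "EPSG:32632"
WGS84 = "EPSG:4326"

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)

_K0 = 0.9996
_LON0 = np.radians(9.0)  # zone 32 central meridian
_FALSE_E = 500000.0


class CRSError(ValueError):
    """Raised for unsupported CRS identifiers."""


def _check(crs: str) -> str:
    crs = crs.upper().strip()
    if crs not in (UTM32N, WGS84):
        raise CRSError(f"unsupported CRS {crs!r}; supported: {UTM32N}, {WGS84}")
    return crs


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def geographic_to_utm32(lon, lat):
    """Forward projection: WGS84 degrees -> UTM32N easting/northing (m)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon)

    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    n = _A / np.sqrt(1 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a = (lam - _LON0) * cos_phi
    m = _meridian_arc(phi)

    east = _FALSE_E + _K0 * n * (
        a
        + (1 - t + c) * a**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120
    )
    north = _K0 * (
        m
        + n
        * tan_phi
        * (
            a**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
        )
    )
    return east, north


def utm32_to_geographic(east, north):
    """Inverse projection: UTM32N easting/northing (m) -> WGS84 degrees."""
    east = np.asarray(east, dtype=float)
    north = np.asarray(north, dtype=float)

    m = north / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))

    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / np.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    d = (east - _FALSE_E) / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6
        / 720
    )
    lam = _LON0 + (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / cos1

    return np.degrees(lam), np.degrees(phi)


def transform(src_crs: str, dst_crs: str, x, y):
    """Transform coordinate arrays between the two supported CRSs.

    For EPSG:4326 the coordinate order is (lon, lat); for EPSG:32632 it is
    (easting, northing).  Same-CRS calls are the identity.
    """
    src, dst = _check(src_crs), _check(dst_crs)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if src == dst:
        return x, y
    if src == WGS84:
        return geographic_to_utm32(x, y)
    return utm32_to_geographic(x, y)
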