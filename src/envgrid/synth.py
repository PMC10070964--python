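"""Seeded synthetic inputs with known ground truth.

Every pipeline stage is exercised on synthetic scenes that emulate the real
inputs — elevation-dependent temperature fields with cloud-induced gaps,
multispectral patches with known index signatures, and heterogeneous
provider station tables — while shipping the truth they were painted from,
so downstream tests are self-checking.  All generators are driven by a
single integer seed through :class:`numpy.random.Generator`; a fixed seed
yields bit-identical output.

Fixture grids are deliberately small (tens to a couple hundred cells per
side) so the full pipeline runs in seconds; every size is configurable
upward through :class:`FixtureConfig`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import crs as _crs
from .grids import GridSpec, RasterLayer
from .lst import OVERPASSES, LstAcquisition
from .indices import BandSet
from .qc import SCL_CLASSES
from .stations import ProviderMapping, Station, StationRecord

__all__ = [
    "FixtureConfig",
    "make_dem",
    "make_lst_scene",
    "make_multispectral_scene",
    "make_station_network",
    "smooth_truth_field",
    "LstSceneBundle",
    "MultispectralBundle",
    "StationNetworkBundle",
]

#: Reflectance signatures used to paint the multispectral patches.  Chosen
#: so NDVI/EVI/MNDWI have known signs and magnitudes inside each patch:
#: vegetation NDVI ~0.84 (inside the declared [0.5, 0.9] band), water MNDWI
#: strictly positive only on the water patch.
_SIGNATURES = {
    "bare": {"blue": 0.06, "green": 0.08, "red": 0.20, "nir": 0.25, "swir": 0.30},
    "vegetation": {"blue": 0.03, "green": 0.06, "red": 0.04, "nir": 0.45, "swir": 0.18},
    "water": {"blue": 0.05, "green": 0.10, "red": 0.04, "nir": 0.02, "swir": 0.01},
}


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic world.

    Defaults describe a 12 km x 12 km tile of the local level: a 60x60
    cell 200 m thermal/DEM grid and a 240x240 cell 10 m reflectance grid,
    1,500 m of relief, the standard environmental lapse rate of
    -0.0065 °C/m, 1 °C observation noise, 30% cloud-induced gaps and a
    40-station ground network.
    """

    seed: int = 0
    origin_x: float = 640_000.0  # round-km corner inside the local extent
    origin_y: float = 5_160_000.0
    dem_cell: float = 200.0
    dem_shape: tuple[int, int] = (60, 60)
    ms_cell: float = 10.0
    ms_shape: tuple[int, int] = (240, 240)
    dem_relief: float = 1500.0
    lapse_rate: float = -0.0065  # °C per meter of elevation
    noise_sd: float = 1.0  # °C
    cloud_fraction: float = 0.3
    n_stations: int = 40
    station_noise_sd: float = 0.5  # field units
    n_hills: int = 4

    def __post_init__(self) -> None:
        for frac in (self.cloud_fraction,):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    def dem_grid(self) -> GridSpec:
        return GridSpec(_crs.UTM32N, self.origin_x, self.origin_y,
                        self.dem_cell, *self.dem_shape)

    def ms_grid(self) -> GridSpec:
        return GridSpec(_crs.UTM32N, self.origin_x, self.origin_y,
                        self.ms_cell, *self.ms_shape)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def make_dem(config: FixtureConfig) -> RasterLayer:
    """Smooth positive elevation surface: a sum of Gaussian hills.

    The surface is rescaled so min >= 0 and max <= ``dem_relief``; zero
    relief gives a perfectly flat DEM.
    """
    grid = config.dem_grid()
    rng = config.rng(salt=1)
    x, y = grid.cell_centers()
    surface = np.zeros(grid.shape)
    span_x = grid.n_cols * grid.cell_size
    span_y = grid.n_rows * grid.cell_size
    for _ in range(config.n_hills):
        cx = grid.origin_x + rng.uniform(0.2, 0.8) * span_x
        cy = grid.origin_y - rng.uniform(0.2, 0.8) * span_y
        sigma = rng.uniform(0.1, 0.3) * min(span_x, span_y)
        amp = rng.uniform(0.4, 1.0)
        surface += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    peak = surface.max()
    if peak > 0 and config.dem_relief > 0:
        surface *= config.dem_relief / peak
    else:
        surface[:] = 0.0
    return RasterLayer(
        grid=grid,
        values=surface,
        nodata_mask=np.zeros(grid.shape, dtype=bool),
        variable="DEM",
        level="LOCAL",
    )


@dataclass
class LstSceneBundle:
    """One synthetic day of thermal acquisitions plus their ground truth."""

    truth: dict[str, RasterLayer]  # by overpass hour tag
    acquisitions: list[LstAcquisition]
    qc: dict[str, RasterLayer]  # by overpass hour tag


#: Sea-level temperature by overpass, °C: a plain diurnal/satellite cycle.
_OVERPASS_T0 = {"TERRA-DAY": 24.0, "AQUA-DAY": 27.0, "TERRA-NIGHT": 12.0, "AQUA-NIGHT": 10.0}


def make_lst_scene(
    config: FixtureConfig,
    dem: RasterLayer,
    date: _dt.date = _dt.date(2020, 7, 1),
) -> LstSceneBundle:
    """Four acquisitions (two satellites x day/night) for one day.

    Truth is sea-level temperature plus lapse-rate cooling with elevation
    plus a smooth spatial anomaly; the observed layers add Gaussian noise
    and flag ``cloud_fraction`` of their pixels as cloud-contaminated in
    the QC band (mandatory QA code 2).
    """
    grid = dem.grid
    x, y = grid.cell_centers()
    span = grid.n_cols * grid.cell_size
    anomaly = 1.5 * np.sin(2 * np.pi * (x - grid.origin_x) / span) * np.cos(
        2 * np.pi * (grid.origin_y - y) / span
    )

    truth: dict[str, RasterLayer] = {}
    acquisitions: list[LstAcquisition] = []
    qc: dict[str, RasterLayer] = {}
    for i, tag in enumerate(OVERPASSES):
        satellite, overpass = tag.split("-")
        rng = config.rng(salt=100 + i)
        true_vals = _OVERPASS_T0[tag] + config.lapse_rate * dem.values + anomaly
        truth[tag] = RasterLayer(
            grid=grid, values=true_vals,
            nodata_mask=np.zeros(grid.shape, bool),
            variable="LST", level="LOCAL", timestamp=date, hour_tag=tag,
        )
        observed = true_vals + rng.normal(0.0, config.noise_sd, grid.shape)
        cloudy = rng.random(grid.shape) < config.cloud_fraction
        qc_vals = np.where(cloudy, 2, 0).astype(float)  # 2: not produced, cloud
        qc[tag] = RasterLayer(
            grid=grid, values=qc_vals,
            nodata_mask=np.zeros(grid.shape, bool),
            variable="QC", level="LOCAL", timestamp=date, hour_tag=tag,
        )
        acquisitions.append(
            LstAcquisition(
                layer=RasterLayer(
                    grid=grid, values=observed,
                    nodata_mask=np.zeros(grid.shape, bool),
                    variable="LST", level="LOCAL", timestamp=date, hour_tag=tag,
                ),
                satellite=satellite,
                overpass=overpass,
                date=date,
            )
        )
    return LstSceneBundle(truth, acquisitions, qc)


@dataclass
class MultispectralBundle:
    bands: BandSet
    scl: RasterLayer
    truth_masks: dict[str, np.ndarray]


def make_multispectral_scene(
    config: FixtureConfig,
    date: _dt.date = _dt.date(2020, 7, 1),
    *,
    band_noise_sd: float = 0.005,
    cloud_fraction: float | None = None,
) -> MultispectralBundle:
    """A 10 m reflectance scene with painted vegetation and water patches.

    A circular vegetation patch and a rectangular water body sit on a bare
    background; the scene-classification layer labels them accordingly and
    paints clouds (class 9) on a random ``cloud_fraction`` of cells.  The
    returned truth masks give the exact painted geometry per feature.
    """
    grid = config.ms_grid()
    rng = config.rng(salt=2)
    if cloud_fraction is None:
        cloud_fraction = 0.0
    rows, cols = np.indices(grid.shape)

    veg_r = min(grid.shape) // 5
    veg_c = (grid.n_rows // 3, grid.n_cols // 3)
    vegetation = (rows - veg_c[0]) ** 2 + (cols - veg_c[1]) ** 2 <= veg_r**2

    water = np.zeros(grid.shape, dtype=bool)
    r0, c0 = int(grid.n_rows * 0.6), int(grid.n_cols * 0.55)
    water[r0 : r0 + grid.n_rows // 6, c0 : c0 + grid.n_cols // 4] = True
    water &= ~vegetation

    cloud = rng.random(grid.shape) < cloud_fraction

    band_values = {}
    for band in ("blue", "green", "red", "nir", "swir"):
        vals = np.full(grid.shape, _SIGNATURES["bare"][band])
        vals[vegetation] = _SIGNATURES["vegetation"][band]
        vals[water] = _SIGNATURES["water"][band]
        vals = np.clip(vals + rng.normal(0.0, band_noise_sd, grid.shape), 0.0, 1.0)
        band_values[band] = RasterLayer(
            grid=grid, values=vals, nodata_mask=np.zeros(grid.shape, bool),
            variable=band.upper(), level="LOCAL", timestamp=date,
        )

    scl_vals = np.full(grid.shape, SCL_CLASSES["NOT_VEGETATED"], dtype=float)
    scl_vals[vegetation] = SCL_CLASSES["VEGETATION"]
    scl_vals[water] = SCL_CLASSES["WATER"]
    scl_vals[cloud] = SCL_CLASSES["CLOUD_HIGH"]
    scl = RasterLayer(
        grid=grid, values=scl_vals, nodata_mask=np.zeros(grid.shape, bool),
        variable="SCL", level="LOCAL", timestamp=date,
    )

    return MultispectralBundle(
        bands=BandSet(date=date, **band_values),
        scl=scl,
        truth_masks={"vegetation": vegetation, "water": water, "cloud": cloud},
    )


def smooth_truth_field(config: FixtureConfig, salt: int = 3) -> Callable:
    """A seeded smooth non-negative scalar field f(x, y) over the tile.

    Used as the precipitation truth behind the station network: a broad
    positive sinusoidal pattern, in mm/day.
    """
    rng = config.rng(salt=salt)
    grid = config.dem_grid()
    span = grid.n_cols * grid.cell_size
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
    base = rng.uniform(5.0, 15.0)
    amp = rng.uniform(2.0, 4.0)

    def field(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return base + amp * (
            np.sin(2 * np.pi * (x - grid.origin_x) / span + phase_x)
            + np.cos(2 * np.pi * (grid.origin_y - y) / span + phase_y)
        )

    return field


#: Two synthetic provider dialects: long Italian-style column names with a
#: day-first date, and terse columns reporting tenths of a unit with an
#: ISO date.  They exercise the mapping machinery end to end.
DIALECTS: dict[str, ProviderMapping] = {
    "AGENCY_A": ProviderMapping(
        provider="AGENCY_A",
        station_col="codice_stazione",
        date_col="data",
        date_format="%d/%m/%Y",
        variable_columns={
            "pioggia_mm": "PREC",
            "temp_max": "TMX2",
            "temp_media": "TMD2",
            "temp_min": "TMN2",
        },
    ),
    "AGENCY_B": ProviderMapping(
        provider="AGENCY_B",
        station_col="id",
        date_col="date",
        date_format="%Y-%m-%d",
        variable_columns={
            "p10": "PREC",
            "tx10": "TMX2",
            "tm10": "TMD2",
            "tn10": "TMN2",
        },
        unit_scale={"PREC": 0.1, "TMX2": 0.1, "TMD2": 0.1, "TMN2": 0.1},
    ),
}


@dataclass
class StationNetworkBundle:
    stations: list[Station]
    records: list[StationRecord]
    provider_tables: dict[str, pd.DataFrame]
    mappings: dict[str, ProviderMapping]
    bad_records: list[StationRecord]


def _serialize_dialect(
    records: list[StationRecord], provider: str, mapping: ProviderMapping
) -> pd.DataFrame:
    col_for = {code: col for col, code in mapping.variable_columns.items()}
    by_day: dict[tuple[str, _dt.date], dict] = {}
    for rec in records:
        row = by_day.setdefault(
            (rec.station_id, rec.date),
            {
                mapping.station_col: rec.station_id,
                mapping.date_col: rec.date.strftime(mapping.date_format),
            },
        )
        scale = mapping.unit_scale.get(rec.variable, 1.0)
        stored = rec.value / scale
        row[col_for[rec.variable]] = round(stored, 6)
    return pd.DataFrame(list(by_day.values()))


def make_station_network(
    config: FixtureConfig,
    truth_field: Callable | None = None,
    dates: Sequence[_dt.date] = (_dt.date(2020, 7, 1),),
    *,
    include_bad_rows: bool = False,
) -> StationNetworkBundle:
    """A ground network sampled from a known smooth precipitation field.

    Stations are placed uniformly over the tile and split between two
    providers; each provider's records are re-serialized into its own
    table dialect (different column names, date formats and unit scalings)
    so the harmonizer can be round-trip tested.  With ``include_bad_rows``
    a few physically impossible records (negative precipitation, inverted
    temperature triples) are injected and also returned separately.
    """
    if truth_field is None:
        truth_field = smooth_truth_field(config)
    grid = config.dem_grid()
    rng = config.rng(salt=4)
    xmin, ymin, xmax, ymax = grid.bounds

    providers = list(DIALECTS)
    stations = []
    for i in range(config.n_stations):
        stations.append(
            Station(
                station_id=f"ST{i:03d}",
                provider=providers[i % len(providers)],
                x=float(rng.uniform(xmin, xmax)),
                y=float(rng.uniform(ymin, ymax)),
                elevation=float(rng.uniform(0.0, config.dem_relief)),
                active_from=_dt.date(2010, 1, 1),
                active_to=None,
            )
        )

    records: list[StationRecord] = []
    for date in dates:
        for st in stations:
            prec = float(truth_field(st.x, st.y))
            prec = max(0.0, prec + float(rng.normal(0.0, config.station_noise_sd)))
            tmean = 20.0 + float(rng.normal(0.0, config.station_noise_sd))
            records.append(StationRecord(st.station_id, date, "PREC", round(prec, 1)))
            records.append(StationRecord(st.station_id, date, "TMD2", round(tmean, 1)))
            records.append(StationRecord(st.station_id, date, "TMX2", round(tmean + 5.0, 1)))
            records.append(StationRecord(st.station_id, date, "TMN2", round(tmean - 5.0, 1)))

    bad_records: list[StationRecord] = []
    if include_bad_rows and stations:
        bad_date = dates[0]
        bad_records = [
            StationRecord(stations[0].station_id, bad_date + _dt.timedelta(days=400), "PREC", -3.0),
            StationRecord(stations[1].station_id, bad_date + _dt.timedelta(days=400), "TMN2", 15.0),
            StationRecord(stations[1].station_id, bad_date + _dt.timedelta(days=400), "TMD2", 10.0),
            StationRecord(stations[1].station_id, bad_date + _dt.timedelta(days=400), "TMX2", 5.0),
        ]

    by_provider: dict[str, list[StationRecord]] = {p: [] for p in providers}
    station_provider = {s.station_id: s.provider for s in stations}
    for rec in records + bad_records:
        by_provider[station_provider[rec.station_id]].append(rec)

    tables = {
        p: _serialize_dialect(recs, p, DIALECTS[p])
        for p, recs in by_provider.items()
    }
    return StationNetworkBundle(stations, records, tables, dict(DIALECTS), bad_records)
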