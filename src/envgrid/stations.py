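"""Ground-station table harmonization, QA and precipitation gridding.

Daily observations arrive from four regional/provincial agencies, each with
its own table dialect (column names, date format, unit scalings).  A
declarative :class:`ProviderMapping` turns each dialect into the common
long schema — one :class:`StationRecord` per (station, date, variable) —
with the variable codes TMX2/TMD2/TMN2 (daily max/mean/min air temperature
at 2 m, °C), PREC (daily precipitation, mm) and UMX2/UMD2/UMN2 (relative
humidity, %).

Cleaned precipitation is interpolated to the 1 km local master grid with a
thin-plate smoothing spline (the same regularized-spline family GIS tools
use for scattered meteorological data); negative interpolated values are
floored at zero.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .grids import GridSpec, RasterLayer

__all__ = [
    "VARIABLE_CODES",
    "Station",
    "StationRecord",
    "ProviderMapping",
    "QARules",
    "RejectedRow",
    "harmonize_provider_table",
    "qa_clean",
    "interpolate_precipitation",
    "StationStore",
]

VARIABLE_CODES = ("TMX2", "TMD2", "TMN2", "PREC", "UMX2", "UMD2", "UMN2")
_TEMPERATURE = {"TMX2", "TMD2", "TMN2"}
_HUMIDITY = {"UMX2", "UMD2", "UMN2"}


@dataclass(frozen=True)
class Station:
    station_id: str
    provider: str
    x: float  # UTM32N easting, m
    y: float  # UTM32N northing, m
    elevation: float  # m
    active_from: _dt.date | None = None
    active_to: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.elevation < -10:
            raise ValueError("elevation below -10 m is not plausible here")


@dataclass(frozen=True)
class StationRecord:
    station_id: str
    date: _dt.date
    variable: str
    value: float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLE_CODES:
            raise ValueError(f"unknown variable code {self.variable!r}")

    @property
    def key(self) -> tuple[str, _dt.date, str]:
        return (self.station_id, self.date, self.variable)


@dataclass(frozen=True)
class RejectedRow:
    """A rejected input row (or record) with the reason for rejection."""

    payload: object
    reason: str


@dataclass(frozen=True)
class ProviderMapping:
    """Declarative description of one provider's table dialect.

    ``variable_columns`` maps source column names to common variable codes;
    ``unit_scale`` gives a multiplicative factor per variable code (e.g.
    0.1 when the provider reports tenths of °C).
    """

    provider: str
    station_col: str
    date_col: str
    date_format: str  # strptime format, e.g. "%d/%m/%Y"
    variable_columns: Mapping[str, str]
    unit_scale: Mapping[str, float] = field(default_factory=dict)
    na_values: frozenset = frozenset({"", "NA", "NaN", "-999", "-9999"})

    def __post_init__(self) -> None:
        for code in self.variable_columns.values():
            if code not in VARIABLE_CODES:
                raise ValueError(f"mapping targets unknown variable {code!r}")


def harmonize_provider_table(
    raw_rows: pd.DataFrame | Sequence[Mapping],
    provider: str,
    mapping: ProviderMapping,
) -> tuple[list[StationRecord], list[RejectedRow]]:
    """Translate one provider's table into common-schema records.

    Wide rows (one column per variable) are melted into long records; unit
    conversions declared in the mapping are applied.  Rows that fail to
    parse (bad date, missing or non-numeric value) are rejected with a
    reason rather than raised.
    """
    if provider != mapping.provider:
        raise ValueError(
            f"table provider {provider!r} does not match mapping for "
            f"{mapping.provider!r}"
        )
    df = pd.DataFrame(raw_rows)
    records: list[StationRecord] = []
    rejected: list[RejectedRow] = []
    if df.empty:
        return records, rejected

    for col in (mapping.station_col, mapping.date_col):
        if col not in df.columns:
            raise ValueError(f"provider table lacks required column {col!r}")

    for row in df.to_dict("records"):
        try:
            date = _dt.datetime.strptime(
                str(row[mapping.date_col]).strip(), mapping.date_format
            ).date()
        except ValueError:
            rejected.append(RejectedRow(row, "bad-date"))
            continue
        station = str(row[mapping.station_col]).strip()
        for src_col, code in mapping.variable_columns.items():
            if src_col not in row:
                continue
            raw = row[src_col]
            text = "" if raw is None else str(raw).strip()
            if text in mapping.na_values or (
                isinstance(raw, float) and np.isnan(raw)
            ):
                rejected.append(
                    RejectedRow({**row, "column": src_col}, "missing-value")
                )
                continue
            try:
                value = float(text)
            except ValueError:
                rejected.append(RejectedRow({**row, "column": src_col}, "bad-value"))
                continue
            # Round after unit conversion: keeps e.g. tenths-of-°C inputs
            # exactly representable and makes dialect round-trips lossless.
            value = round(value * mapping.unit_scale.get(code, 1.0), 9)
            records.append(StationRecord(station, date, code, value))
    return records, rejected


@dataclass(frozen=True)
class QARules:
    """Plausibility and consistency rules applied after harmonization."""

    temperature_range: tuple[float, float] = (-50.0, 50.0)
    precipitation_range: tuple[float, float] = (0.0, 1000.0)
    humidity_range: tuple[float, float] = (0.0, 100.0)
    enforce_temperature_ordering: bool = True

    def range_for(self, code: str) -> tuple[float, float]:
        if code in _TEMPERATURE:
            return self.temperature_range
        if code == "PREC":
            return self.precipitation_range
        return self.humidity_range


def qa_clean(
    records: Iterable[StationRecord], rules: QARules = QARules()
) -> tuple[list[StationRecord], list[RejectedRow]]:
    """Split records into accepted and rejected-with-reasons.

    Identical duplicates are collapsed (extra copies rejected as
    ``duplicate``); records sharing a key but disagreeing on the value are
    all rejected (``conflict``); out-of-range values are rejected
    (``range``); and a station-day whose min/mean/max temperatures violate
    TMN2 <= TMD2 <= TMX2 has all three rejected (``ordering``).  Accepted
    plus rejected always partition the input.
    """
    records = list(records)
    accepted: list[StationRecord] = []
    rejected: list[RejectedRow] = []

    # Duplicate handling.
    by_key: dict[tuple, list[StationRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.key, []).append(rec)
    survivors: list[StationRecord] = []
    for key, group in by_key.items():
        values = {g.value for g in group}
        if len(values) > 1:
            rejected.extend(RejectedRow(g, "conflict") for g in group)
        else:
            survivors.append(group[0])
            rejected.extend(RejectedRow(g, "duplicate") for g in group[1:])

    # Range rules.
    in_range: list[StationRecord] = []
    for rec in survivors:
        lo, hi = rules.range_for(rec.variable)
        if not (lo <= rec.value <= hi):
            rejected.append(RejectedRow(rec, "range"))
        else:
            in_range.append(rec)

    # Temperature-ordering rule per station-day.
    if rules.enforce_temperature_ordering:
        temps: dict[tuple[str, _dt.date], dict[str, StationRecord]] = {}
        for rec in in_range:
            if rec.variable in _TEMPERATURE:
                temps.setdefault((rec.station_id, rec.date), {})[rec.variable] = rec
        bad_keys = set()
        for sd_key, trio in temps.items():
            present = [trio[c].value for c in ("TMN2", "TMD2", "TMX2") if c in trio]
            ordered = all(a <= b for a, b in zip(present, present[1:]))
            if not ordered:
                bad_keys.add(sd_key)
        for rec in in_range:
            if (
                rec.variable in _TEMPERATURE
                and (rec.station_id, rec.date) in bad_keys
            ):
                rejected.append(RejectedRow(rec, "ordering"))
            else:
                accepted.append(rec)
    else:
        accepted = in_range

    return accepted, rejected


def interpolate_precipitation(
    day_records: Iterable[StationRecord],
    stations: Iterable[Station],
    target: GridSpec,
    *,
    smoothing: float = 0.1,
    min_stations: int = 5,
    date: _dt.date | None = None,
) -> RasterLayer:
    """Daily station precipitation -> continuous 1 km surface.

    A thin-plate smoothing spline (regularized spline family; ``smoothing``
    in field units, 0 for exact interpolation at the stations) is fitted to
    the day's PREC records at the station coordinates and evaluated at
    every cell center of the target grid.  Negative values are floored at
    zero; the result has no nodata cells.
    """
    station_by_id = {s.station_id: s for s in stations}
    pts, vals = [], []
    the_date = date
    for rec in day_records:
        if rec.variable != "PREC":
            continue
        if the_date is None:
            the_date = rec.date
        elif rec.date != the_date:
            raise ValueError("day_records span more than one date")
        st = station_by_id.get(rec.station_id)
        if st is None:
            continue
        pts.append((st.x, st.y))
        vals.append(rec.value)
    if len(pts) < min_stations:
        raise ValueError(
            f"only {len(pts)} stations with PREC on {the_date}; "
            f"need at least {min_stations}"
        )

    pts_arr = np.asarray(pts, float)
    vals_arr = np.asarray(vals, float)
    # Kilometre coordinates keep the spline system well conditioned.
    center = pts_arr.mean(axis=0)
    rbf = RBFInterpolator(
        (pts_arr - center) / 1000.0,
        vals_arr,
        kernel="thin_plate_spline",
        smoothing=smoothing,
    )
    x, y = target.cell_centers()
    query = (np.column_stack([x.ravel(), y.ravel()]) - center) / 1000.0
    surface = rbf(query).reshape(target.shape)
    surface = np.maximum(surface, 0.0)
    return RasterLayer(
        grid=target,
        values=surface,
        nodata_mask=np.zeros(target.shape, dtype=bool),
        variable="PREC",
        level="LOCAL",
        timestamp=the_date,
    )


class StationStore:
    """Flat in-memory store of stations and harmonized records.

    Mirrors a plain relational layout (station registry plus one long
    observation table) and supports the per-station series queries the
    downstream covariates need.  Persistence is CSV via
    :meth:`to_frames` / :meth:`from_frames`.
    """

    def __init__(
        self,
        stations: Iterable[Station] = (),
        records: Iterable[StationRecord] = (),
    ) -> None:
        self.stations: dict[str, Station] = {s.station_id: s for s in stations}
        self._records: list[StationRecord] = list(records)

    def add_records(self, records: Iterable[StationRecord]) -> None:
        self._records.extend(records)

    def __len__(self) -> int:
        return len(self._records)

    def records_for_date(self, date: _dt.date, variable: str) -> list[StationRecord]:
        return [
            r for r in self._records if r.date == date and r.variable == variable
        ]

    def query_station_series(
        self,
        variable: str,
        station_id: str,
        date_range: tuple[_dt.date, _dt.date],
    ) -> list[StationRecord]:
        """Date-sorted records for one station/variable; gaps preserved."""
        if station_id not in self.stations:
            raise KeyError(f"unknown station {station_id!r}")
        start, end = date_range
        hits = [
            r
            for r in self._records
            if r.station_id == station_id
            and r.variable == variable
            and start <= r.date <= end
        ]
        return sorted(hits, key=lambda r: r.date)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        st = pd.DataFrame(
            [dataclasses.asdict(s) for s in self.stations.values()]
        )
        rec = pd.DataFrame([dataclasses.asdict(r) for r in self._records])
        return st, rec

    @classmethod
    def from_frames(
        cls, stations: pd.DataFrame, records: pd.DataFrame
    ) -> "StationStore":
        def _date(v):
            if isinstance(v, _dt.date):
                return v
            return pd.Timestamp(v).date() if pd.notna(v) else None

        st = [
            Station(
                str(r["station_id"]),
                str(r["provider"]),
                float(r["x"]),
                float(r["y"]),
                float(r["elevation"]),
                _date(r.get("active_from")),
                _date(r.get("active_to")),
            )
            for r in stations.to_dict("records")
        ]
        rec = [
            StationRecord(
                str(r["station_id"]), _date(r["date"]), str(r["variable"]),
                float(r["value"]),
            )
            for r in records.to_dict("records")
        ]
        return cls(st, rec)
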