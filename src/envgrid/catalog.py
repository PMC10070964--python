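"""Product registry, naming convention and the file-based catalog.

Every artifact the pipelines emit is named
``{VARIABLE}_{LEVEL}_{YYYYMMDD}[_{TAG}].{ext}`` — e.g.
``LST_LOCAL_20200112_TERRA-DAY.tif`` — so a plain directory doubles as a
queryable catalog: files can be found by variable, level, date range and
(for the thermal product) overpass tag, and a product's expected timeline
can be checked for completeness against its cadence.

The product registry pins, per (variable, level, source), the target cell
size and temporal cadence of the published dataset (the machine-readable
twin of the dataset summary table), and backs the resolution-snapping rule
of :func:`envgrid.grids.snap_resolution`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml


__all__ = [
    "ProductSpec",
    "CatalogEntry",
    "PRODUCT_REGISTRY",
    "get_product",
    "encode_name",
    "parse_name",
    "NameParseError",
    "query_catalog",
    "completeness_report",
    "load_registry",
    "save_registry",
]

logger = logging.getLogger(__name__)

LEVEL_CODES = ("LOCAL", "COUNTRY", "CONTINENTAL")
CADENCES = ("daily", "8-day", "16-day", "static", "irregular")


@dataclass(frozen=True)
class ProductSpec:
    """Registry entry fixing a product's published resolution and cadence."""

    variable: str
    level: str
    source: str
    target_cell_size: float | None  # meters; None = keep native
    cadence: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVEL_CODES:
            raise ValueError(f"unknown level {self.level!r}")
        if self.cadence not in CADENCES:
            raise ValueError(f"unknown cadence {self.cadence!r}")


def _registry(entries: Iterable[ProductSpec]) -> dict:
    return {(e.variable, e.level, e.source): e for e in entries}


#: Default product registry.  The explicit target cell sizes carry the
#: published per-product resolutions (e.g. the 0.25-degree gridded-station
#: precipitation product is distributed at 27 km, the 0.1-degree satellite
#: product at 10 km) that a naive degree-to-km rounding cannot reproduce.
PRODUCT_REGISTRY: dict = _registry(
    [
        ProductSpec("LST", "LOCAL", "MODIS", 200.0, "daily", "degC"),
        ProductSpec("LST", "COUNTRY", "MODIS", 1000.0, "8-day", "degC"),
        ProductSpec("LST", "CONTINENTAL", "MODIS", 1000.0, "8-day", "degC"),
        ProductSpec("NDVI", "LOCAL", "SENTINEL2", 200.0, "irregular", ""),
        ProductSpec("NDVI", "COUNTRY", "MODIS", 1000.0, "8-day", ""),
        ProductSpec("NDVI", "CONTINENTAL", "MODIS", 1000.0, "8-day", ""),
        ProductSpec("EVI", "LOCAL", "SENTINEL2", 200.0, "irregular", ""),
        ProductSpec("EVI", "COUNTRY", "MODIS", 1000.0, "8-day", ""),
        ProductSpec("EVI", "CONTINENTAL", "MODIS", 1000.0, "8-day", ""),
        ProductSpec("MNDWI", "LOCAL", "SENTINEL2", 200.0, "irregular", ""),
        ProductSpec("PREC", "LOCAL", "STATIONS", 1000.0, "daily", "mm/day"),
        ProductSpec("PREC", "COUNTRY", "E-OBS", 27000.0, "daily", "mm/day"),
        ProductSpec("PREC", "CONTINENTAL", "E-OBS", 27000.0, "daily", "mm/day"),
        ProductSpec("PREC", "COUNTRY", "GPM", 10000.0, "daily", "mm/day"),
        ProductSpec("PREC", "CONTINENTAL", "GPM", 10000.0, "daily", "mm/day"),
        ProductSpec("DEM", "LOCAL", "SPOT", 200.0, "static", "m"),
        ProductSpec("LANDCOVER", "CONTINENTAL", "CORINE", 100.0, "static", ""),
    ]
)


def get_product(
    variable: str,
    level: str,
    source: str | None = None,
    registry: dict | None = None,
) -> ProductSpec:
    """Look up a registry entry; source may be omitted when unambiguous."""
    registry = PRODUCT_REGISTRY if registry is None else registry
    if source is not None:
        try:
            return registry[(variable, level, source)]
        except KeyError:
            raise KeyError(
                f"no registry entry for {variable}/{level}/{source}"
            ) from None
    hits = [e for (v, l, _), e in registry.items() if v == variable and l == level]
    if not hits:
        raise KeyError(f"no registry entry for {variable}/{level}")
    if len(hits) > 1:
        sources = sorted(e.source for e in hits)
        raise KeyError(
            f"{variable}/{level} is ambiguous (sources {sources}); pass source="
        )
    return hits[0]


# ---------------------------------------------------------------------------
# Naming convention

_NAME_RE = re.compile(
    r"^(?P<variable>[A-Z][A-Z0-9]*)_"
    r"(?P<level>LOCAL|COUNTRY|CONTINENTAL)_"
    r"(?P<date>\d{8})"
    r"(?:_(?P<tag>[A-Z][A-Z0-9-]*))?"
    r"\.(?P<ext>[A-Za-z0-9]+)$"
)


class NameParseError(ValueError):
    """Malformed catalog filename; carries the failing position."""

    def __init__(self, filename: str, position: int, message: str) -> None:
        super().__init__(f"{filename!r} at position {position}: {message}")
        self.filename = filename
        self.position = position


@dataclass(frozen=True)
class CatalogEntry:
    """A named, dated, queryable artifact on disk."""

    path: Path
    variable: str
    level: str
    date: _dt.date
    hour_tag: str | None = None

    def checksum(self) -> str:
        """SHA-256 of the file contents (computed lazily on request)."""
        return hashlib.sha256(Path(self.path).read_bytes()).hexdigest()


def encode_name(
    variable: str,
    level: str,
    date: _dt.date,
    hour_tag: str | None = None,
    ext: str = "tif",
) -> str:
    """Canonical filename for an artifact."""
    if level not in LEVEL_CODES:
        raise ValueError(f"unknown level {level!r}")
    if not re.fullmatch(r"[A-Z][A-Z0-9]*", variable):
        raise ValueError(f"variable code {variable!r} must be upper-case alphanumeric")
    if hour_tag is not None and not re.fullmatch(r"[A-Z][A-Z0-9-]*", hour_tag):
        raise ValueError(f"hour tag {hour_tag!r} must be upper-case alphanumeric/dash")
    parts = [variable, level, date.strftime("%Y%m%d")]
    if hour_tag:
        parts.append(hour_tag)
    return "_".join(parts) + f".{ext}"


def parse_name(filename: str) -> CatalogEntry:
    """Parse a canonical filename back to its fields (inverse of encode)."""
    name = Path(filename).name
    m = _NAME_RE.match(name)
    if not m:
        # Locate the first offending component for the error message.
        parts = name.split("_")
        if not re.fullmatch(r"[A-Z][A-Z0-9]*", parts[0] or ""):
            raise NameParseError(name, 0, "expected upper-case variable code")
        if len(parts) < 2 or parts[1].split(".")[0] not in LEVEL_CODES:
            raise NameParseError(name, len(parts[0]) + 1, "expected level code")
        pos = len(parts[0]) + len(parts[1]) + 2
        raise NameParseError(name, pos, "expected YYYYMMDD date")
    try:
        date = _dt.datetime.strptime(m.group("date"), "%Y%m%d").date()
    except ValueError:
        raise NameParseError(name, m.start("date"), "invalid calendar date") from None
    return CatalogEntry(
        path=Path(filename),
        variable=m.group("variable"),
        level=m.group("level"),
        date=date,
        hour_tag=m.group("tag"),
    )


# ---------------------------------------------------------------------------
# Catalog queries

_CATALOG_EXTS = {".tif", ".tiff", ".nc", ".csv"}


def query_catalog(
    root: str | Path,
    variable: str | None = None,
    level: str | None = None,
    date_range: tuple[_dt.date, _dt.date] | None = None,
    hour_tag: str | None = None,
) -> list[CatalogEntry]:
    """Entries under ``root`` matching all provided filters, date-sorted.

    Files that do not follow the naming convention are skipped with a
    logged warning; results depend only on directory contents and filters,
    not on listing order.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    entries = []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in _CATALOG_EXTS:
            continue
        try:
            entry = parse_name(path.name)
        except NameParseError as exc:
            logger.warning("skipping uncatalogable file: %s", exc)
            continue
        entry = dataclasses.replace(entry, path=path)
        if variable is not None and entry.variable != variable:
            continue
        if level is not None and entry.level != level:
            continue
        if hour_tag is not None and entry.hour_tag != hour_tag:
            continue
        if date_range is not None and not (date_range[0] <= entry.date <= date_range[1]):
            continue
        entries.append(entry)
    return sorted(entries, key=lambda e: (e.date, e.variable, e.hour_tag or ""))


def expected_dates(
    cadence: str, period: tuple[_dt.date, _dt.date]
) -> list[_dt.date]:
    """The expected artifact dates of a cadence over a period.

    Daily: every day.  8-day / 16-day: window starts at day-of-year 1, 9,
    17, ... (resp. 1, 17, 33, ...), restarting every year; a start date is
    expected when it falls inside the period.
    """
    start, end = period
    if cadence == "daily":
        n = (end - start).days + 1
        return [start + _dt.timedelta(days=i) for i in range(n)]
    if cadence in ("8-day", "16-day"):
        step = 8 if cadence == "8-day" else 16
        dates = []
        for year in range(start.year, end.year + 1):
            d = _dt.date(year, 1, 1)
            while d < _dt.date(year + 1, 1, 1):
                if start <= d <= end:
                    dates.append(d)
                d += _dt.timedelta(days=step)
        return dates
    if cadence == "static":
        return []
    raise ValueError(f"cadence {cadence!r} has no defined timeline")


def completeness_report(
    catalog: Sequence[CatalogEntry] | str | Path,
    product: ProductSpec,
    period: tuple[_dt.date, _dt.date],
) -> pd.DataFrame:
    """Expected-vs-present table for one product over a period.

    Returns a DataFrame with one row per expected date and a boolean
    ``present`` column; missing dates are the rows with ``present=False``.
    """
    if isinstance(catalog, (str, Path)):
        entries = query_catalog(catalog, variable=product.variable, level=product.level)
    else:
        entries = [
            e
            for e in catalog
            if e.variable == product.variable and e.level == product.level
        ]
    have = {e.date for e in entries}
    expected = expected_dates(product.cadence, period)
    return pd.DataFrame(
        {
            "date": expected,
            "present": [d in have for d in expected],
        }
    )


# ---------------------------------------------------------------------------
# Registry persistence (plain-text config)


def save_registry(registry: dict, path: str | Path) -> Path:
    path = Path(path)
    payload = [dataclasses.asdict(e) for e in registry.values()]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_registry(path: str | Path) -> dict:
    payload = yaml.safe_load(Path(path).read_text())
    return _registry(ProductSpec(**item) for item in payload)
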