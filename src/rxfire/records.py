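"""Core fire-record model and tabular I/O.

A fire record is one satellite detection or one burn-permit entry: a point
location (WGS84), a local calendar date, a burned area in acres, and a burn
type that starts UNKNOWN and is resolved downstream (agricultural burn,
wildfire, prescribed burn, or invalid).  Record sets are thin wrappers around
a pandas DataFrame with a fixed column schema, carrying the data source and
a provenance dict (file of origin, rows dropped on read, filters applied).

Column layouts of permit exports differ by state agency and satellite-product
versions drift, so the readers take a configurable column map; best-effort
defaults are shipped for common layouts.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

__all__ = [
    "ACRE_M2",
    "EARTH_RADIUS_M",
    "Source",
    "BurnType",
    "FireRecord",
    "RecordSet",
    "RegionBoundary",
    "read_records",
    "write_records",
    "clean_permits",
    "haversine_m",
    "to_acres",
]

#: Exact international definition: 1 acre = 4046.8564224 m^2.
ACRE_M2 = 4046.8564224

#: Mean Earth radius (IUGG), meters.
EARTH_RADIUS_M = 6_371_008.8


class Source(str, enum.Enum):
    """Provenance of a record set."""

    FINN = "FINN"        # satellite-derived fire inventory detections
    PERMIT = "PERMIT"    # state burn-permit records
    WFIGS = "WFIGS"      # interagency wildfire reference records
    TRUTH = "TRUTH"      # synthetic ground truth


class BurnType(str, enum.Enum):
    UNKNOWN = "UNKNOWN"
    PRESCRIBED = "PRESCRIBED"
    AGRICULTURAL = "AGRICULTURAL"
    WILDFIRE = "WILDFIRE"
    INVALID = "INVALID"


#: Canonical column order of the tabular representation.
COLUMNS = [
    "id",
    "longitude",
    "latitude",
    "date",
    "area",
    "burn_type",
    "state",
    "land_cover_class",
]


@dataclass(frozen=True)
class FireRecord:
    """One fire detection or permit entry (scalar view of a RecordSet row)."""

    id: str
    source: Source
    longitude: float
    latitude: float
    date: pd.Timestamp
    area: float
    burn_type: BurnType = BurnType.UNKNOWN
    state: str | None = None
    land_cover_class: int | None = None


class RecordSet:
    """An ordered collection of fire records from a single source.

    Parameters
    ----------
    df:
        DataFrame with (at least) the canonical columns.  Extra columns are
        preserved (the synthetic generator uses them for event bookkeeping).
    source:
        Common :class:`Source` of every record in the set.
    provenance:
        Free-form metadata: input file, column map, drop counts, filters.
    """

    def __init__(self, df: pd.DataFrame, source: Source, provenance: dict | None = None):
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col == "burn_type":
                    df[col] = BurnType.UNKNOWN.value
                elif col in ("state",):
                    df[col] = pd.NA
                elif col == "land_cover_class":
                    df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
                else:
                    raise ValueError(f"record table is missing required column {col!r}")
        df["id"] = df["id"].astype(str)
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df["land_cover_class"] = df["land_cover_class"].astype("Int64")
        self._validate(df)
        # canonical columns first, extras after, stable row order
        extras = [c for c in df.columns if c not in COLUMNS]
        self.df = df[COLUMNS + extras].reset_index(drop=True)
        self.source = Source(source)
        self.provenance: dict = dict(provenance or {})

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].head(3).tolist()
            raise ValueError(f"duplicate record ids: {dupes}")
        lat = df["latitude"].to_numpy(float)
        lon = df["longitude"].to_numpy(float)
        if len(lat) and (np.nanmin(lat) < -90 or np.nanmax(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if len(lon) and (np.nanmin(lon) < -180 or np.nanmax(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
        bad = set(df["burn_type"]) - {t.value for t in BurnType}
        if bad:
            raise ValueError(f"unknown burn types: {sorted(bad)}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield FireRecord(
                id=row.id,
                source=self.source,
                longitude=row.longitude,
                latitude=row.latitude,
                date=row.date,
                area=row.area,
                burn_type=BurnType(row.burn_type),
                state=None if pd.isna(row.state) else row.state,
                land_cover_class=None if pd.isna(row.land_cover_class) else int(row.land_cover_class),
            )

    def copy(self) -> "RecordSet":
        return RecordSet(self.df.copy(), self.source, dict(self.provenance))

    def with_df(self, df: pd.DataFrame, note: Mapping | None = None) -> "RecordSet":
        prov = dict(self.provenance)
        if note:
            prov.update(note)
        return RecordSet(df, self.source, prov)

    def select(self, burn_type: BurnType) -> "RecordSet":
        """Subset of records with the given burn type."""
        return self.with_df(self.df[self.df["burn_type"] == burn_type.value])

    def type_counts(self) -> dict[str, int]:
        return self.df["burn_type"].value_counts().to_dict()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RecordSet({self.source.value}, n={len(self)})"


@dataclass
class RegionBoundary:
    """A named region (e.g. a state) given by closed polygon rings in WGS84."""

    name: str
    polygon: object  # shapely (Multi)Polygon

    def __post_init__(self):
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("boundary polygon must enclose a positive area")

    def contains(self, lon: float, lat: float) -> bool:
        """Closed test: points exactly on the boundary edge count as inside."""
        return bool(self.polygon.covers(Point(lon, lat)))

    @classmethod
    def from_geojson(cls, path: str | Path, name: str | None = None) -> "RegionBoundary":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            feat = gj["features"][0]
        elif gj.get("type") == "Feature":
            feat = gj
        else:
            feat = {"geometry": gj, "properties": {}}
        geom = shape(feat["geometry"])
        name = name or feat.get("properties", {}).get("name", Path(path).stem)
        return cls(name=name, polygon=geom)


# ---------------------------------------------------------------------------
# unit handling

_UNIT_TO_ACRES = {
    "acres": 1.0,
    "m2": 1.0 / ACRE_M2,
    "hectares": 10_000.0 / ACRE_M2,
}


def to_acres(area, unit: str):
    """Convert burned area to acres.  ``unit`` is one of acres/m2/hectares."""
    try:
        factor = _UNIT_TO_ACRES[unit]
    except KeyError:
        raise ValueError(f"unknown area unit {unit!r}; expected one of {sorted(_UNIT_TO_ACRES)}")
    return np.asarray(area, dtype=float) * factor if np.ndim(area) else float(area) * factor


# ---------------------------------------------------------------------------
# readers / writers

#: Best-effort column maps for common layouts.  Keys are canonical field
#: names, values are source-file column headers.  State permit schemas are
#: not standardized; override per file as needed.
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "canonical": {f: f for f in ("id", "longitude", "latitude", "date", "area", "burn_type", "state", "land_cover_class")},
    "finn": {"id": "FIREID", "longitude": "LONGI", "latitude": "LATI", "date": "DAY", "area": "AREA", "land_cover_class": "GENVEG"},
    "permit_fl": {"id": "PERMIT_ID", "longitude": "LONGITUDE", "latitude": "LATITUDE", "date": "BURN_DATE", "area": "ACRES", "burn_type": "BURN_TYPE"},
    "permit_sc": {"id": "PERMIT_ID", "longitude": "LONGITUDE", "latitude": "LATITUDE", "date": "DATE", "area": "ACRES"},
    "permit_ga": {"id": "PERMIT_ID", "longitude": "LONGITUDE", "latitude": "LATITUDE", "date": "DATE", "area": "ACRES"},
    "wfigs": {"id": "OBJECTID", "longitude": "X", "latitude": "Y", "date": "FireDiscoveryDateTime", "area": "DailyAcres"},
}


def read_records(
    path: str | Path,
    source: Source | str,
    column_map: Mapping[str, str] | str = "canonical",
    unit: str = "acres",
) -> RecordSet:
    """Read a CSV of fire records into a :class:`RecordSet`.

    Rows whose coordinates or dates do not parse are dropped and counted in
    ``provenance['dropped']``.  Areas are converted to acres on read.

    Parameters
    ----------
    column_map:
        Either a mapping from canonical field names (``id``, ``longitude``,
        ``latitude``, ``date``, ``area``; optionally ``burn_type``, ``state``,
        ``land_cover_class``) to file column headers, or the name of a shipped
        default layout (one of ``canonical``, ``finn``, ``permit_fl``,
        ``permit_sc``, ``permit_ga``, ``wfigs``).
    unit:
        Unit of the area column: ``acres``, ``m2`` or ``hectares``.
    """
    source = Source(source)
    if isinstance(column_map, str):
        try:
            column_map = DEFAULT_COLUMN_MAPS[column_map]
        except KeyError:
            raise ValueError(f"no default column map named {column_map!r}")
    required = ["id", "longitude", "latitude", "date", "area"]
    missing_fields = [f for f in required if f not in column_map]
    if missing_fields:
        raise ValueError(f"column map must name columns for {missing_fields}")

    raw = pd.read_csv(path, dtype=str)
    if raw.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
    missing_cols = [c for f, c in column_map.items() if f in required and c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: mapped columns not found in file: {missing_cols}")
    # optional fields mapped to absent columns are simply skipped
    column_map = {f: c for f, c in column_map.items() if c in raw.columns}

    df = pd.DataFrame({field: raw[col] for field, col in column_map.items()})
    n_in = len(df)
    df["longitude"] = pd.to_numeric(df["longitude"], errors="coerce")
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    df["area"] = pd.to_numeric(df.get("area"), errors="coerce")
    df["date"] = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    if "land_cover_class" in df:
        df["land_cover_class"] = pd.to_numeric(df["land_cover_class"], errors="coerce").astype("Int64")
    bad = df["longitude"].isna() | df["latitude"].isna() | df["date"].isna()
    df = df[~bad]
    df["area"] = to_acres(df["area"].to_numpy(float), unit)
    if "burn_type" in df:
        df["burn_type"] = df["burn_type"].fillna(BurnType.UNKNOWN.value)

    prov = {
        "file": str(path),
        "column_map": dict(column_map),
        "unit": unit,
        "rows_read": n_in,
        "dropped": int(bad.sum()),
    }
    return RecordSet(df, source, prov)


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a record set as canonical CSV (round-trip stable with
    :func:`read_records` under the canonical column map)."""
    out = rs.df[COLUMNS].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# permit cleaning

def clean_permits(rs: RecordSet, boundary: RegionBoundary) -> RecordSet:
    """Drop permit records with invalid burned area or out-of-region location.

    A record is removed for exactly one reason, checked in order: burned area
    missing or ≤ 0 first, then location outside the region boundary (points
    exactly on the edge are kept).  Removal counts per reason are recorded in
    provenance.
    """
    if rs.source is not Source.PERMIT:
        raise ValueError(f"clean_permits expects a PERMIT record set, got {rs.source.value}")
    df = rs.df
    bad_area = df["area"].isna() | (df["area"] <= 0)
    inside = np.fromiter(
        (boundary.contains(lon, lat) for lon, lat in zip(df["longitude"], df["latitude"])),
        dtype=bool,
        count=len(df),
    )
    out_of_bounds = ~bad_area & ~inside
    keep = ~bad_area & inside
    note = {
        "cleaned_against": boundary.name,
        "removed_invalid_area": int(bad_area.sum()),
        "removed_out_of_boundary": int(out_of_bounds.sum()),
    }
    return rs.with_df(df[keep], note)


# ---------------------------------------------------------------------------
# geodesy

def haversine_m(a, b) -> np.ndarray | float:
    """Great-circle distance in meters between lon/lat points.

    ``a`` and ``b`` are ``(lon, lat)`` pairs in decimal degrees, or arrays of
    shape ``(n, 2)``; broadcasting follows numpy rules.  Uses the mean Earth
    radius :data:`EARTH_RADIUS_M`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d
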