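"""Fire-activity export and simplified land-cover-based emissions.

Smoke modeling frameworks consume a fire-activity file: one row per fire
with location, date/time, burned area, and fire type.  Neither permits nor
satellite products report burn hours, so prescribed burns are assumed to
start at 11:00 local time (crews begin late morning) and end before 18:00;
duration is looked up from burned area in a configurable step table.

Emissions are estimated inventory-style, per record and species:

    E_s [kg] = area [m^2] * fuel_load [kg/m^2] * combustion_completeness * EF_s [g/kg] / 1000

with fuel load, completeness, and emission factors per land-cover group.
The shipped factor table is a placeholder of literature-style magnitudes
and is plain configuration — override it for any fidelity run.  Comparison
utilities pair two emission sets per fire, per day, or per grid cell/date
and summarize each species with a through-origin regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjustment import RegressionFit, fit_through_origin
from .landcover import DEFAULT_GROUP_MAP, Group, LandCoverGrid, dominant_land_cover, vintage_for_year
from .matching import GridDefinition
from .records import ACRE_M2, BurnType, RecordSet

__all__ = [
    "DEFAULT_DURATION_TABLE",
    "DEFAULT_EMISSION_FACTORS",
    "EmissionFactors",
    "EmissionRecord",
    "estimate_duration",
    "export_bluesky_activity",
    "read_activity",
    "estimate_emissions",
    "compare_emissions",
]

#: (area threshold in acres, duration in hours): the smallest row whose
#: threshold is >= the burned area applies; larger burns get the 7 h cap
#: implied by the 11:00-18:00 burn window.
DEFAULT_DURATION_TABLE: tuple[tuple[float, float], ...] = (
    (10.0, 1.0),
    (50.0, 2.0),
    (100.0, 3.0),
    (500.0, 4.0),
    (1000.0, 5.0),
)

MAX_DURATION_H = 7.0
START_HOUR = 11  # local clock time prescribed burns are assumed to ignite


@dataclass(frozen=True)
class EmissionFactors:
    """Per-land-cover-group fuel and emission parameters.

    fuel_load in kg/m^2, combustion_completeness in (0, 1], emission
    factors in grams of species per kg of fuel burned.
    """

    fuel_load: float
    combustion_completeness: float
    ef: Mapping[str, float]

    def __post_init__(self):
        if not (0.0 < self.combustion_completeness <= 1.0):
            raise ValueError("combustion_completeness must be in (0, 1]")
        if self.fuel_load < 0 or any(v < 0 for v in self.ef.values()):
            raise ValueError("fuel load and emission factors must be non-negative")


#: Placeholder table with forest-like and cropland-like magnitudes; pure
#: configuration, not a claim about any operational product.
DEFAULT_EMISSION_FACTORS: dict[Group, EmissionFactors] = {
    Group.OTHER: EmissionFactors(
        fuel_load=1.2, combustion_completeness=0.45,
        ef={"CO": 85.0, "PM2.5": 12.0, "PM10": 14.0},
    ),
    Group.AGRICULTURE: EmissionFactors(
        fuel_load=0.6, combustion_completeness=0.85,
        ef={"CO": 60.0, "PM2.5": 6.0, "PM10": 7.0},
    ),
}


@dataclass(frozen=True)
class EmissionRecord:
    """Per-record emitted mass by species, kg."""

    record_id: str
    masses: Mapping[str, float]


def estimate_duration(area_acres: float, table: Sequence[tuple[float, float]] = DEFAULT_DURATION_TABLE) -> float:
    """Burn duration in hours from burned area via a step table.

    The table is ordered by strictly increasing area threshold; the first
    row with ``area <= threshold`` applies.  Areas above every threshold get
    the 7-hour cap (an 11:00 start must end by 18:00).
    """
    table = list(table)
    if not table:
        raise ValueError("duration table must have at least one row")
    thresholds = [t for t, _ in table]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("duration-table thresholds must be strictly increasing")
    if any(h > MAX_DURATION_H for _, h in table):
        raise ValueError(f"durations cannot exceed {MAX_DURATION_H} h (11:00-18:00 window)")
    for threshold, hours in table:
        if area_acres <= threshold:
            return float(hours)
    return MAX_DURATION_H


_ACTIVITY_COLUMNS = ["id", "latitude", "longitude", "date_time", "end_time", "area_acres", "fire_type"]


def export_bluesky_activity(
    rs: RecordSet,
    durations: Sequence[tuple[float, float]] = DEFAULT_DURATION_TABLE,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Build a fire-locations activity table (optionally written as CSV).

    One row per typed record: prescribed burns as ``RX``, wildfires as
    ``WF``, both with an assumed 11:00 local start and an area-dependent
    duration; rows are ordered by date then id.  Untyped (UNKNOWN) records
    are an error — finalize types first.
    """
    df = rs.df
    if (df["burn_type"] == BurnType.UNKNOWN.value).any():
        raise ValueError("record set contains UNKNOWN burn types; run the typing pipeline first")
    typed = df[df["burn_type"].isin([BurnType.PRESCRIBED.value, BurnType.WILDFIRE.value])]
    typed = typed.sort_values(["date", "id"], kind="mergesort")
    rows = []
    for row in typed.itertuples(index=False):
        hours = estimate_duration(row.area, durations)
        start = row.date + pd.Timedelta(hours=START_HOUR)
        end = start + pd.Timedelta(hours=hours)
        rows.append({
            "id": row.id,
            "latitude": row.latitude,
            "longitude": row.longitude,
            "date_time": start.isoformat(),
            "end_time": end.isoformat(),
            "area_acres": row.area,
            "fire_type": "RX" if row.burn_type == BurnType.PRESCRIBED.value else "WF",
        })
    out = pd.DataFrame(rows, columns=_ACTIVITY_COLUMNS)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def read_activity(path: str | Path) -> pd.DataFrame:
    """Read back an exported activity file (round-trip counterpart)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity file missing columns {missing}")
    return df


def _resolve_group(row, lc_by_year: Mapping[int, LandCoverGrid] | None,
                   group_map: Mapping[int, Group]) -> Group:
    if lc_by_year:
        vintages = sorted(lc_by_year)
        lc = lc_by_year[vintage_for_year(row.date.year, vintages)]
        _, group = dominant_land_cover(row.longitude, row.latitude, row.area, lc)
        return group
    if not pd.isna(row.land_cover_class):
        return group_map.get(int(row.land_cover_class), Group.OTHER)
    raise ValueError(f"record {row.id}: no land-cover raster and no stored class code")


def estimate_emissions(
    rs: RecordSet,
    eft: Mapping[Group, EmissionFactors] = DEFAULT_EMISSION_FACTORS,
    lc_by_year: Mapping[int, LandCoverGrid] | None = None,
    group_map: Mapping[int, Group] = DEFAULT_GROUP_MAP,
) -> list[EmissionRecord]:
    """Per-record, per-species emitted mass in kg.

    The land-cover group comes from the raster stack if given, else from
    the record's stored class code.  A group absent from the factor table
    raises an error naming the group.
    """
    out = []
    for row in rs.df.itertuples(index=False):
        group = _resolve_group(row, lc_by_year, group_map)
        if group not in eft:
            raise KeyError(f"no emission factors configured for land-cover group {group.value}")
        fx = eft[group]
        base = row.area * ACRE_M2 * fx.fuel_load * fx.combustion_completeness
        out.append(EmissionRecord(
            record_id=row.id,
            masses={s: base * g_per_kg / 1000.0 for s, g_per_kg in fx.ef.items()},
        ))
    return out


def _keyed(emissions: Sequence[EmissionRecord], rs: RecordSet | None, scale: str,
           grid: GridDefinition | None) -> dict:
    """species -> {key -> summed mass}; key depends on the comparison scale."""
    if scale == "per_fire":
        key_of = {e.record_id: e.record_id for e in emissions}
    else:
        if rs is None:
            raise ValueError(f"scale {scale!r} needs the record sets to resolve dates/cells")
        df = rs.df.set_index("id")
        if scale == "daily_total":
            key_of = {rid: df.loc[rid, "date"] for rid in df.index}
        elif scale == "grid":
            if grid is None:
                raise ValueError("scale 'grid' needs a GridDefinition")
            key_of = {}
            for rid in df.index:
                x, y = grid.crs.to_xy(df.loc[rid, "longitude"], df.loc[rid, "latitude"])
                cell = grid.cell_of(float(x), float(y))
                if cell is not None:
                    key_of[rid] = (df.loc[rid, "date"], cell)
        else:
            raise ValueError(f"unknown comparison scale {scale!r}")
    keyed: dict[str, dict] = {}
    for e in emissions:
        if e.record_id not in key_of:
            continue
        k = key_of[e.record_id]
        for species, mass in e.masses.items():
            keyed.setdefault(species, {}).setdefault(k, 0.0)
            keyed[species][k] += mass
    return keyed


def compare_emissions(
    a: Sequence[EmissionRecord],
    b: Sequence[EmissionRecord],
    scale: str = "per_fire",
    records_a: RecordSet | None = None,
    records_b: RecordSet | None = None,
    grid: GridDefinition | None = None,
) -> dict[str, RegressionFit]:
    """Through-origin regression of emission set b on set a, per species.

    ``scale`` chooses the pairing key: ``per_fire`` (record ids),
    ``daily_total`` (calendar dates, masses summed per day), or ``grid``
    (date and grid cell).  Raises if the two sets share no keys.
    """
    ka = _keyed(a, records_a, scale, grid)
    kb = _keyed(b, records_b, scale, grid)
    fits: dict[str, RegressionFit] = {}
    for species in sorted(set(ka) & set(kb)):
        shared = sorted(set(ka[species]) & set(kb[species]), key=str)
        if not shared:
            continue
        pairs = [(ka[species][k], kb[species][k]) for k in shared]
        fits[species] = fit_through_origin(pairs)
    if not fits:
        raise ValueError(f"no overlapping keys between emission sets at scale {scale!r}")
    return fits
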