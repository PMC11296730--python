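"""Matching satellite and permit prescribed-burn records at three scales.

Satellite detections and burn permits describe the same burns with
different errors: permit locations and dates are manager-reported plans,
satellite locations carry sensor geolocation error, and one physical burn
can appear as several detection points ("segmentation").  Matching is
therefore done at three spatial scales:

* **statewide** — daily total burned area per region (temporal pattern only);
* **fire-to-fire** — one-to-one pairing of individual records, either by
  nearest distance on the same date, or relaxed in distance/date with the
  burned-area difference selecting among admissible candidates;
* **grid-based** — burned area aggregated to cells of a common grid
  (default 4 km) per date, pairing cell values where both sources report
  burning; an optional 3x3 moving-mean sampling mitigates burns that
  straddle cell boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._proj import LocalEquirectangular
from .records import BurnType, RecordSet, haversine_m

__all__ = [
    "DailyTotalSeries",
    "MatchedPair",
    "GridDefinition",
    "GriddedField",
    "statewide_daily",
    "match_nearest",
    "match_relaxed",
    "grid_burned_area",
    "smooth_3x3",
    "match_grid",
]


@dataclass
class DailyTotalSeries:
    """Daily total burned area (acres) for one region."""

    region: str
    entries: dict[pd.Timestamp, float]


@dataclass(frozen=True)
class MatchedPair:
    finn_id: str
    permit_id: str
    distance_m: float
    date_diff_days: int
    area_diff_acres: float


@dataclass(frozen=True)
class GridDefinition:
    """Regular analysis grid: lower-left origin, half-open square cells.

    A point at ``(x, y)`` belongs to cell ``(ix, iy)`` with
    ``ix = floor((x - x0)/cell)`` — points exactly on an interior edge fall
    in the higher-index cell.
    """

    crs: LocalEquirectangular
    x0: float
    y0: float
    cell: float = 4000.0
    nx: int = 1
    ny: int = 1

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        ix = int(np.floor((x - self.x0) / self.cell))
        iy = int(np.floor((y - self.y0) / self.cell))
        if 0 <= ix < self.nx and 0 <= iy < self.ny:
            return ix, iy
        return None


@dataclass
class GriddedField:
    """Per-date burned-area (or emission) field on a grid, acres per cell."""

    grid: GridDefinition
    date: pd.Timestamp
    values: np.ndarray  # shape (ny, nx), [iy, ix]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("field shape does not match grid definition")


def statewide_daily(rs: RecordSet, region: str) -> DailyTotalSeries:
    """Daily total prescribed burned area in a region.

    Only PRESCRIBED records contribute.  If the set carries state codes the
    region filters on them; otherwise all records are assumed in-region.
    """
    df = rs.df
    df = df[df["burn_type"] == BurnType.PRESCRIBED.value]
    if df["state"].notna().any():
        df = df[df["state"] == region]
    totals = df.groupby("date")["area"].sum()
    return DailyTotalSeries(region=region, entries={d: float(v) for d, v in totals.items()})


# ---------------------------------------------------------------------------
# fire-to-fire matching

def _prescribed(rs: RecordSet, who: str) -> pd.DataFrame:
    df = rs.df
    bad = df["burn_type"] != BurnType.PRESCRIBED.value
    if bad.any():
        raise ValueError(f"{who} set contains non-PRESCRIBED records; type it first")
    return df


def _candidates(finn: pd.DataFrame, permits: pd.DataFrame,
                max_distance_m: float, max_days: int) -> pd.DataFrame:
    """All (finn, permit) pairs within the distance and date gates."""
    rows = []
    f_xy = finn[["longitude", "latitude"]].to_numpy(float)
    p_xy = permits[["longitude", "latitude"]].to_numpy(float)
    f_day = finn["date"].to_numpy()
    p_day = permits["date"].to_numpy()
    for i in range(len(finn)):
        ddays = np.abs((p_day - f_day[i]) / np.timedelta64(1, "D")).astype(int)
        near_t = ddays <= max_days
        if not near_t.any():
            continue
        d = haversine_m(f_xy[i], p_xy[near_t])
        ok = d <= max_distance_m
        if not np.any(ok):
            continue
        for j, dist in zip(np.flatnonzero(near_t)[ok], np.atleast_1d(d)[ok]):
            rows.append((
                finn["id"].iat[i], permits["id"].iat[j], float(dist),
                int(ddays[j]), abs(float(finn["area"].iat[i] - permits["area"].iat[j])),
            ))
    return pd.DataFrame(rows, columns=["finn_id", "permit_id", "distance_m", "date_diff_days", "area_diff_acres"])


def _greedy(cands: pd.DataFrame, sort_cols: list[str]) -> set[MatchedPair]:
    """One-to-one greedy acceptance in the given priority order.

    Ties beyond the metric columns break on id order, making the result a
    total order and hence independent of input record order.
    """
    out: set[MatchedPair] = set()
    if cands.empty:
        return out
    cands = cands.sort_values(sort_cols + ["finn_id", "permit_id"], kind="mergesort")
    used_f: set[str] = set()
    used_p: set[str] = set()
    for row in cands.itertuples(index=False):
        if row.finn_id in used_f or row.permit_id in used_p:
            continue
        used_f.add(row.finn_id)
        used_p.add(row.permit_id)
        out.add(MatchedPair(row.finn_id, row.permit_id, row.distance_m,
                            row.date_diff_days, row.area_diff_acres))
    return out


def match_nearest(finn: RecordSet, permits: RecordSet, max_distance_m: float) -> set[MatchedPair]:
    """Same-date nearest-distance matching.

    Candidate pairs share a calendar date and lie within ``max_distance_m``;
    the globally closest pair is accepted, both records retired, and the
    process repeats — a deterministic one-to-one assignment.
    """
    f = _prescribed(finn, "satellite")
    p = _prescribed(permits, "permit")
    cands = _candidates(f, p, max_distance_m, max_days=0)
    return _greedy(cands, ["distance_m"])


def match_relaxed(finn: RecordSet, permits: RecordSet,
                  max_distance_m: float, max_days: int) -> set[MatchedPair]:
    """Relaxed matching: gates on distance and date, selects on area.

    Pairs within ``max_distance_m`` and ``max_days`` are candidates; they
    are accepted one-to-one in ascending burned-area difference (ties:
    ascending distance, then id order).  The study's reference relaxation is
    1500 m and 3 days.
    """
    if max_days < 0:
        raise ValueError("max_days must be >= 0")
    f = _prescribed(finn, "satellite")
    p = _prescribed(permits, "permit")
    cands = _candidates(f, p, max_distance_m, max_days)
    return _greedy(cands, ["area_diff_acres", "distance_m"])


# ---------------------------------------------------------------------------
# grid-based matching

def grid_burned_area(rs: RecordSet, grid: GridDefinition) -> list[GriddedField]:
    """Aggregate record burned areas onto the grid, one field per date.

    Each record's full area lands in the single cell containing its point;
    out-of-domain records are excluded.  Total in-domain area is conserved
    exactly (before any smoothing).
    """
    df = rs.df
    x, y = grid.crs.to_xy(df["longitude"].to_numpy(float), df["latitude"].to_numpy(float))
    ix = np.floor((np.atleast_1d(x) - grid.x0) / grid.cell).astype(int)
    iy = np.floor((np.atleast_1d(y) - grid.y0) / grid.cell).astype(int)
    inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    pts = pd.DataFrame({
        "date": df["date"].to_numpy(),
        "ix": ix, "iy": iy,
        "area": df["area"].to_numpy(float),
    })[inside]
    fields = []
    for date, sub in pts.groupby("date"):
        vals = np.zeros((grid.ny, grid.nx))
        np.add.at(vals, (sub["iy"].to_numpy(), sub["ix"].to_numpy()), sub["area"].to_numpy())
        fields.append(GriddedField(grid=grid, date=pd.Timestamp(date), values=vals))
    return fields


def smooth_3x3(field: GriddedField) -> GriddedField:
    """Replace each cell by the mean of its 3x3 window.

    At domain edges the mean runs over the in-domain part of the window
    (2x3 at edges, 2x2 at corners), so a constant field stays constant and
    no negative values can appear.
    """
    kernel = np.ones((3, 3))
    num = ndimage.convolve(field.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(field.values), kernel, mode="constant", cval=0.0)
    return GriddedField(grid=field.grid, date=field.date, values=num / den)


def match_grid(finn_fields: Sequence[GriddedField],
               permit_fields: Sequence[GriddedField]) -> list[tuple[float, float]]:
    """Pair cell values where both sources report burning on the same date.

    Returns ``(finn_value, permit_value)`` for every (date, cell) with
    strictly positive burned area in both field lists.  All fields must
    share one grid definition.
    """
    grids = {f.grid for f in list(finn_fields) + list(permit_fields)}
    if len(grids) > 1:
        raise ValueError("all fields must share a single grid definition")
    f_by_date = {f.date: f for f in finn_fields}
    p_by_date = {f.date: f for f in permit_fields}
    pairs: list[tuple[float, float]] = []
    for date in sorted(set(f_by_date) & set(p_by_date)):
        fv = f_by_date[date].values
        pv = p_by_date[date].values
        mask = (fv > 0) & (pv > 0)
        pairs.extend(zip(fv[mask].tolist(), pv[mask].tolist()))
    return pairs
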