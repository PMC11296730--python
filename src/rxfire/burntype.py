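"""Burn-type differentiation.

Satellite fire inventories report every thermally detected fire without
saying what kind of burn it was.  Three rules resolve the type:

* **Agricultural** — the dominant land cover under the fire's square
  footprint is agriculture; fires over open water or barren land are marked
  invalid (almost certainly bad coordinates).
* **Wildfire** — prescribed burns start and end the same day, so any fire
  that persists across days is treated as a wildfire.  Detections are linked
  into events with a two-predicate graph: same-day detections within the
  spatial clustering distance (default 1000 m), consecutive-day detections
  within the temporal clustering distance (default 800 m); events are the
  connected components, and every member of a component spanning two or more
  days is flagged WILDFIRE.  The two distances are tuned by the elbow (knee)
  of the cluster-count-versus-distance curve.
* **Prescribed** — whatever remains after the first two rules.

The ordering matters and mirrors the processing chain: agricultural burns
are removed before wildfire detection, and the prescribed label is the
remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import BallTree

from .landcover import Group, LandCoverGrid, LandCoverError, dominant_land_cover, vintage_for_year
from .records import EARTH_RADIUS_M, BurnType, RecordSet, Source

__all__ = [
    "WildfireCluster",
    "ElbowCurve",
    "WildfireDetector",
    "AgriculturalLandCoverClassifier",
    "spatiotemporal_cluster",
    "detect_wildfires",
    "classify_agricultural",
    "finalize_types",
    "elbow_tune",
]


@dataclass
class WildfireCluster:
    """A connected set of detections forming one candidate fire event."""

    member_ids: frozenset[str]
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    total_area: float

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


class WildfireDetector(ClusterMixin, BaseEstimator):
    """Spatio-temporal clustering of fire detections into events.

    Two detections are linked when they occur on the same calendar date
    within ``spatial_distance_m`` of each other, or on consecutive dates
    within ``temporal_distance_m``; events are the transitive closure of
    these links.  A multi-day event is a wildfire.

    Parameters
    ----------
    spatial_distance_m : float, default 1000
        Same-day linking distance (great-circle meters).
    temporal_distance_m : float, default 800
        Consecutive-day linking distance (great-circle meters).
    link_mode : {'both', 'spatial', 'temporal'}, default 'both'
        Which link predicates to build.  Single-predicate modes exist for
        parameter tuning of one distance at a time.

    Attributes
    ----------
    labels_ : ndarray of int, shape (n,)
        Component id per input row (dense, 0-based, first-appearance order).
    clusters_ : list of WildfireCluster
    n_clusters_ : int
    """

    def __init__(self, spatial_distance_m: float = 1000.0, temporal_distance_m: float = 800.0,
                 link_mode: str = "both"):
        self.spatial_distance_m = spatial_distance_m
        self.temporal_distance_m = temporal_distance_m
        self.link_mode = link_mode

    def fit(self, X, y=None):
        """Cluster detections.

        ``X`` is a DataFrame with columns ``longitude``, ``latitude``,
        ``date`` (and optionally ``id``, ``area``), or a RecordSet.
        """
        if isinstance(X, RecordSet):
            X = X.df
        if self.link_mode not in ("both", "spatial", "temporal"):
            raise ValueError(f"unknown link_mode {self.link_mode!r}")
        if self.link_mode in ("both", "spatial") and not self.spatial_distance_m > 0:
            raise ValueError("spatial_distance_m must be positive")
        if self.link_mode in ("both", "temporal") and not self.temporal_distance_m > 0:
            raise ValueError("temporal_distance_m must be positive")
        df = pd.DataFrame({
            "longitude": np.asarray(X["longitude"], dtype=float),
            "latitude": np.asarray(X["latitude"], dtype=float),
            "date": pd.to_datetime(np.asarray(X["date"])),
        })
        ids = np.asarray(X["id"]).astype(str) if "id" in X else np.arange(len(df)).astype(str)
        areas = np.asarray(X["area"], dtype=float) if "area" in X else np.zeros(len(df))

        n = len(df)
        uf = _UnionFind(n)
        day = (df["date"] - pd.Timestamp("2000-01-01")).dt.days.to_numpy()
        # canonical order inside each day group keeps the link set independent
        # of input row order (the graph is order-free anyway)
        by_day: dict[int, np.ndarray] = {
            d: idx.to_numpy() for d, idx in df.groupby(day).groups.items()
        }
        rad = np.radians(df[["latitude", "longitude"]].to_numpy())

        def link(src: np.ndarray, dst: np.ndarray, dist_m: float, same: bool) -> None:
            tree = BallTree(rad[dst], metric="haversine")
            hits = tree.query_radius(rad[src], r=dist_m / EARTH_RADIUS_M)
            for a, nbrs in zip(src, hits):
                for b in dst[nbrs]:
                    if not (same and a == b):
                        uf.union(int(a), int(b))

        days_sorted = sorted(by_day)
        for d in days_sorted:
            if self.link_mode in ("both", "spatial"):
                link(by_day[d], by_day[d], self.spatial_distance_m, same=True)
            if self.link_mode in ("both", "temporal") and (d + 1) in by_day:
                link(by_day[d], by_day[d + 1], self.temporal_distance_m, same=False)

        roots = np.fromiter((uf.find(i) for i in range(n)), dtype=int, count=n)
        _, labels = np.unique(roots, return_inverse=True)
        # renumber in first-appearance order for determinism
        order = {}
        for lab in labels:
            order.setdefault(int(lab), len(order))
        self.labels_ = np.fromiter((order[int(l)] for l in labels), dtype=int, count=n)

        clusters = []
        cdf = pd.DataFrame({"label": self.labels_, "id": ids, "date": df["date"], "area": areas})
        for lab, grp in cdf.groupby("label"):
            clusters.append(
                WildfireCluster(
                    member_ids=frozenset(grp["id"]),
                    start_date=grp["date"].min(),
                    end_date=grp["date"].max(),
                    total_area=float(grp["area"].sum()),
                )
            )
        self.clusters_ = clusters
        self.n_clusters_ = len(clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def spatiotemporal_cluster(
    rs: RecordSet, d_spatial: float, d_temporal: float
) -> list[WildfireCluster]:
    """Cluster a record set into candidate fire events (see WildfireDetector)."""
    det = WildfireDetector(d_spatial, d_temporal).fit(rs)
    return det.clusters_


def detect_wildfires(
    rs: RecordSet, d_spatial: float = 1000.0, d_temporal: float = 800.0
) -> RecordSet:
    """Flag members of multi-day detection clusters as wildfires.

    Only UNKNOWN records participate (agricultural and invalid records have
    already been resolved and must not seed wildfire chains).  Every member
    of a cluster whose duration is two days or more becomes WILDFIRE;
    single-day clusters are untouched.
    """
    if rs.source is not Source.FINN and rs.source is not Source.TRUTH:
        raise ValueError("wildfire detection applies to satellite-derived record sets")
    df = rs.df.copy()
    mask = df["burn_type"] == BurnType.UNKNOWN.value
    sub = df[mask]
    if len(sub) == 0:
        return rs.with_df(df, {"wildfires_flagged": 0})
    clusters = spatiotemporal_cluster(rs.with_df(sub), d_spatial, d_temporal)
    fire_ids: set[str] = set()
    for cl in clusters:
        if cl.duration_days >= 2:
            fire_ids.update(cl.member_ids)
    hit = df["id"].isin(fire_ids) & mask
    df.loc[hit, "burn_type"] = BurnType.WILDFIRE.value
    return rs.with_df(df, {
        "wildfire_detection": {"d_spatial_m": d_spatial, "d_temporal_m": d_temporal},
        "wildfires_flagged": int(hit.sum()),
    })


class AgriculturalLandCoverClassifier(BaseEstimator):
    """Label records by the dominant land cover under their footprint.

    AGRICULTURE -> AGRICULTURAL burn; WATER or BARREN -> INVALID (assumed
    wrong coordinates); anything else leaves the record's type unchanged.
    Records that cannot be placed on a raster are flagged in provenance and
    left unchanged.

    Parameters
    ----------
    lc_by_year : mapping of vintage year -> LandCoverGrid
        A fire in year Y uses the latest vintage <= Y.
    """

    def __init__(self, lc_by_year: dict[int, LandCoverGrid]):
        self.lc_by_year = lc_by_year

    def transform(self, rs: RecordSet) -> RecordSet:
        if not self.lc_by_year:
            raise ValueError("lc_by_year must map at least one vintage year to a raster")
        vintages = sorted(self.lc_by_year)
        df = rs.df.copy()
        unresolved: list[str] = []
        types = df["burn_type"].to_numpy(dtype=object)
        codes = df["land_cover_class"].copy()
        rows = zip(df.index, df["id"], df["longitude"], df["latitude"], df["date"], df["area"])
        for pos, (idx, rid, lon, lat, date, area) in enumerate(rows):
            if types[pos] != BurnType.UNKNOWN.value:
                continue
            lc = self.lc_by_year[vintage_for_year(date.year, vintages)]
            try:
                code, group = dominant_land_cover(lon, lat, area, lc)
            except LandCoverError:
                unresolved.append(rid)
                continue
            codes.at[idx] = code
            if group is Group.AGRICULTURE:
                types[pos] = BurnType.AGRICULTURAL.value
            elif group in (Group.WATER, Group.BARREN):
                types[pos] = BurnType.INVALID.value
        df["burn_type"] = types
        df["land_cover_class"] = codes
        return rs.with_df(df, {"landcover_unresolved": unresolved})

    def fit(self, X=None, y=None):  # stateless; present for pipeline duck-typing
        return self

    def fit_transform(self, rs: RecordSet, y=None) -> RecordSet:
        return self.transform(rs)


def classify_agricultural(rs: RecordSet, lc_by_year: dict[int, LandCoverGrid]) -> RecordSet:
    """Functional wrapper over :class:`AgriculturalLandCoverClassifier`."""
    return AgriculturalLandCoverClassifier(lc_by_year).transform(rs)


def finalize_types(rs: RecordSet) -> RecordSet:
    """Resolve remaining UNKNOWN records to PRESCRIBED and drop INVALID ones.

    Run after agricultural classification (and, for satellite sets, wildfire
    detection): what is neither agricultural nor a wildfire is a prescribed
    burn, and invalid records (water/barren coordinates) leave the set.
    """
    df = rs.df.copy()
    unknown = df["burn_type"] == BurnType.UNKNOWN.value
    df.loc[unknown, "burn_type"] = BurnType.PRESCRIBED.value
    invalid = df["burn_type"] == BurnType.INVALID.value
    return rs.with_df(df[~invalid], {
        "finalized_prescribed": int(unknown.sum()),
        "dropped_invalid": int(invalid.sum()),
    })


# ---------------------------------------------------------------------------
# elbow tuning

@dataclass
class ElbowCurve:
    """Cluster count as a function of clustering distance, with its knee.

    ``distances`` may be scalars (single-distance modes) or (spatial,
    temporal) pairs (joint mode); ``axis`` holds the scalar x-values the
    curvature was computed on.
    """

    distances: list
    counts: list[int]
    knee: object
    curvature: list[float]


def _knee_index(xs: np.ndarray, counts: np.ndarray) -> int:
    """Index of maximum discrete curvature of the normalized curve.

    Both axes are min-max normalized; curvature is the centered second
    difference, so only interior candidates can be the knee.  A flat or
    perfectly linear curve has no knee.
    """
    if len(xs) < 4:
        raise ValueError("elbow tuning needs at least 4 candidate distances")
    if counts.max() == counts.min():
        raise ValueError("no knee: cluster counts are constant over the candidates")
    cn = (counts - counts.min()) / (counts.max() - counts.min())
    xn = (xs - xs.min()) / (xs.max() - xs.min())
    # non-uniform-spacing second difference
    curv = np.zeros(len(xs))
    for i in range(1, len(xs) - 1):
        h1, h2 = xn[i] - xn[i - 1], xn[i + 1] - xn[i]
        curv[i] = 2.0 * (h1 * cn[i + 1] - (h1 + h2) * cn[i] + h2 * cn[i - 1]) / (h1 * h2 * (h1 + h2))
    if np.max(curv) <= 1e-9:
        raise ValueError("no knee: curve has no positive curvature")
    return int(np.argmax(curv)), curv


def elbow_tune(rs: RecordSet, candidates, mode: str = "joint") -> ElbowCurve:
    """Pick a clustering distance at the knee of the count-vs-distance curve.

    Parameters
    ----------
    candidates:
        Ordered distances in meters.  For ``mode='joint'`` these are
        ``(spatial, temporal)`` pairs varied together; for ``'spatial'`` /
        ``'temporal'`` they are scalars and only that link predicate is used.
    mode : {'spatial', 'temporal', 'joint'}

    Returns
    -------
    ElbowCurve with the selected distance in ``knee``.
    """
    candidates = list(candidates)
    if len(candidates) < 4:
        raise ValueError("elbow tuning needs at least 4 candidate distances")
    counts = []
    for cand in candidates:
        if mode == "joint":
            ds, dt = cand
            det = WildfireDetector(ds, dt, link_mode="both")
        elif mode == "spatial":
            det = WildfireDetector(spatial_distance_m=float(cand), link_mode="spatial")
        elif mode == "temporal":
            det = WildfireDetector(temporal_distance_m=float(cand), link_mode="temporal")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        counts.append(det.fit(rs).n_clusters_)
    xs = np.asarray([c[0] if mode == "joint" else c for c in candidates], dtype=float)
    if not np.all(np.diff(xs) > 0):
        raise ValueError("candidate distances must be strictly increasing")
    idx, curv = _knee_index(xs, np.asarray(counts, dtype=float))
    return ElbowCurve(
        distances=candidates,
        counts=[int(c) for c in counts],
        knee=candidates[idx],
        curvature=[float(c) for c in curv],
    )
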