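"""Synthetic fire scenarios with paired permit and satellite views.

The processing chain (burn typing, matching, burned-area adjustment) is
validated on generated scenarios in which the ground truth is known.  A
scenario holds:

* **truth** — prescribed burns (single-day, on non-agricultural land),
  agricultural burns (on cropland patches), and wildfires (multi-day chains
  of detections whose daily centers step a bounded distance), placed on a
  generated land-cover raster;
* **permit view** — prescribed and agricultural truth burns as a land
  manager would report them: jittered location, possibly shifted date (a
  permit records the planned day, not necessarily the burn day), and an
  independently noisy area estimate;
* **satellite view** — every truth burn detected with a probability that
  rises with burned area (small fires are missed), jittered location, area
  multiplied by a systematic bias with multiplicative noise, and large
  burns optionally split into several detection points whose areas sum to
  the observed total (segmentation);
* **links** — the truth-to-view correspondence, for scoring.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._proj import LocalEquirectangular
from .landcover import DEFAULT_GROUP_MAP, Group, LandCoverGrid
from .records import ACRE_M2, BurnType, RecordSet, Source, write_records

__all__ = [
    "WildfireConfig",
    "ObservationConfig",
    "ScenarioConfig",
    "SyntheticScenario",
    "generate_truth",
    "observe",
    "score_classification",
]

_FOREST = 42  # background class (evergreen forest)
_CROP = 82
_WATER = 11
_BARREN = 31


@dataclass
class WildfireConfig:
    """Multi-day wildfire chains: day count, daily step, detections/day."""

    days: tuple[int, int] = (2, 4)
    step_m: tuple[float, float] = (300.0, 700.0)
    detections_per_day: tuple[int, int] = (1, 3)
    detection_scatter_m: float = 40.0
    area_median_acres: float = 60.0
    area_logsd: float = 0.8


@dataclass
class ObservationConfig:
    """How the permit and satellite views distort the truth."""

    permit_loc_jitter_m: float = 300.0
    finn_loc_jitter_m: float = 200.0
    permit_date_jitter_days: int = 1
    permit_area_logsd: float = 0.15
    area_bias: float = 0.66
    area_noise_logsd: float = 0.25
    detect_midpoint_acres: float = 5.0
    detect_steepness: float = 2.0
    detect_max: float = 1.0
    seg_area_acres: float = 100.0
    seg_max_fragments: int = 3

    def detect_prob(self, area_acres) -> np.ndarray:
        """Logistic-in-log-area detection probability (monotone in area)."""
        a = np.maximum(np.asarray(area_acres, dtype=float), 1e-9)
        z = self.detect_steepness * (np.log10(a) - math.log10(self.detect_midpoint_acres))
        return self.detect_max / (1.0 + np.exp(-z))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    seed: int = 0
    domain: tuple[float, float, float, float] = (-83.0, 31.0, -82.5, 31.5)  # lon/lat box
    start_date: str = "2019-01-01"
    n_days: int = 90
    n_prescribed: int = 500
    n_agricultural: int = 100
    n_wildfire: int = 10
    area_median_acres: float = 25.0
    area_logsd: float = 1.0
    ag_area_median_acres: float = 20.0
    ag_area_logsd: float = 0.7
    prescribed_min_separation_m: float = 0.0  # >0 enforces isolation between burn sites
    landcover_cell_m: float = 30.0
    n_ag_patches: int = 40
    ag_patch_m: tuple[float, float] = (800.0, 2500.0)
    n_water_patches: int = 5
    water_patch_m: tuple[float, float] = (1000.0, 3000.0)
    n_barren_patches: int = 5
    barren_patch_m: tuple[float, float] = (400.0, 1000.0)
    wildfire: WildfireConfig = field(default_factory=WildfireConfig)
    obs: ObservationConfig = field(default_factory=ObservationConfig)

    @classmethod
    def bias_recovery(cls, area_bias: float = 0.66, seed: int = 0, **kwargs) -> "ScenarioConfig":
        """Study conditions for validating the burned-area adjustment.

        The adjustment slope is a consistent estimator of the configured
        bias only when the two views see the same burn mass in matched
        cells, so detection is complete, permit dates are true, and large
        burns are not segmented.  Multiplicative area noise and location
        jitter stay on.  Under the full default discrepancy structure
        (partial detection, date error, segmentation) matched cells lose
        mass asymmetrically and the fitted slope attenuates by several
        percent — the realistic condition, reported separately.
        """
        cfg = cls(seed=seed, **kwargs)
        cfg.obs.area_bias = area_bias
        cfg.obs.detect_midpoint_acres = 1e-3  # every burn detected
        cfg.obs.permit_date_jitter_days = 0
        cfg.obs.seg_max_fragments = 1
        return cfg

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        wf = d.pop("wildfire", {})
        obs = d.pop("obs", {})
        cfg = cls(**d)
        if wf:
            cfg.wildfire = WildfireConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in wf.items()})
        if obs:
            cfg.obs = ObservationConfig(**obs)
        return cfg


# ---------------------------------------------------------------------------
# land cover

def _generate_landcover(cfg: ScenarioConfig, rng: np.random.Generator):
    lon0, lat0, lon1, lat1 = cfg.domain
    crs = LocalEquirectangular((lon0 + lon1) / 2.0, (lat0 + lat1) / 2.0)
    (xa, ya) = crs.to_xy(lon0, lat0)
    (xb, yb) = crs.to_xy(lon1, lat1)
    if xb <= xa or yb <= ya:
        raise ValueError("domain bounding box has zero area")
    cell = cfg.landcover_cell_m
    nx = int(math.floor((xb - xa) / cell))
    ny = int(math.floor((yb - ya) / cell))
    classes = np.full((ny, nx), _FOREST, dtype=np.int16)

    def stamp(n_patches, size_range, code):
        boxes = []  # absolute projected coordinates
        for _ in range(n_patches):
            w = rng.uniform(*size_range)
            h = rng.uniform(*size_range)
            px = rng.uniform(xa, xa + nx * cell - w)
            py = rng.uniform(ya, ya + ny * cell - h)
            i0, i1 = int((px - xa) / cell), int((px + w - xa) / cell)
            j0, j1 = int((py - ya) / cell), int((py + h - ya) / cell)
            classes[j0:j1, i0:i1] = code
            boxes.append((px, py, px + w, py + h))
        return boxes

    # water/barren first so cropland patches are never overwritten
    stamp(cfg.n_water_patches, cfg.water_patch_m, _WATER)
    stamp(cfg.n_barren_patches, cfg.barren_patch_m, _BARREN)
    ag_boxes = stamp(cfg.n_ag_patches, cfg.ag_patch_m, _CROP)
    lc = LandCoverGrid(classes=classes, x0=float(xa), y0=float(ya), cell_size=cell,
                       crs=crs, year=pd.Timestamp(cfg.start_date).year,
                       group_map=dict(DEFAULT_GROUP_MAP))
    return lc, ag_boxes


class _OtherSampler:
    """Rejection-sample points whose square neighborhood is all background.

    Uses a summed-area table over the non-background mask for O(1) window
    checks.
    """

    def __init__(self, lc: LandCoverGrid):
        self.lc = lc
        mask = (lc.classes != _FOREST).astype(np.int64)
        self.sat = np.zeros((lc.ny + 1, lc.nx + 1), dtype=np.int64)
        np.cumsum(np.cumsum(mask, axis=0), axis=1, out=self.sat[1:, 1:])

    def _window_clear(self, x: float, y: float, half_m: float) -> bool:
        lc = self.lc
        c = lc.cell_size
        i0 = max(int((x - half_m - lc.x0) / c), 0)
        i1 = min(int((x + half_m - lc.x0) / c) + 1, lc.nx)
        j0 = max(int((y - half_m - lc.y0) / c), 0)
        j1 = min(int((y + half_m - lc.y0) / c) + 1, lc.ny)
        if i0 >= i1 or j0 >= j1:
            return False
        s = self.sat
        return (s[j1, i1] - s[j0, i1] - s[j1, i0] + s[j0, i0]) == 0

    def sample(self, rng: np.random.Generator, half_m: float,
               keepout: list[tuple[float, float]] | None = None,
               min_sep_m: float = 0.0, tries: int = 100):
        lc = self.lc
        min_half = 2.0 * lc.cell_size
        # progressively relax the clearance window if the domain is crowded;
        # the point itself always stays on background land
        for half in (half_m, half_m / 2.0, half_m / 4.0, min_half):
            half = max(half, min_half)
            x_lo, x_hi = lc.x0 + half, lc.x0 + lc.nx * lc.cell_size - half
            y_lo, y_hi = lc.y0 + half, lc.y0 + lc.ny * lc.cell_size - half
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            for _ in range(tries):
                x = rng.uniform(x_lo, x_hi)
                y = rng.uniform(y_lo, y_hi)
                if not self._window_clear(x, y, half):
                    continue
                if min_sep_m > 0 and keepout:
                    d2min = min((x - px) ** 2 + (y - py) ** 2 for px, py in keepout)
                    if d2min < min_sep_m ** 2:
                        continue
                return x, y
        raise RuntimeError("could not place a burn on background land; domain too crowded")


def _lognormal(rng, median, logsd, size=None):
    return median * np.exp(rng.normal(0.0, logsd, size=size))


def generate_truth(cfg: ScenarioConfig) -> tuple[RecordSet, LandCoverGrid]:
    """Generate ground-truth burns and their land-cover raster.

    Deterministic given ``cfg.seed``.  The returned set carries true burn
    types and, for wildfires, an ``event_id`` column grouping the daily
    detections of one fire.
    """
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 0])
    lc, ag_boxes = _generate_landcover(cfg, rng)
    sampler = _OtherSampler(lc)
    start = pd.Timestamp(cfg.start_date)
    crs = lc.crs

    rows = []
    sites: list[tuple[float, float]] = []
    min_sep = cfg.prescribed_min_separation_m

    # prescribed burns: single day, background land
    for k in range(cfg.n_prescribed):
        area = float(_lognormal(rng, cfg.area_median_acres, cfg.area_logsd))
        side = math.sqrt(area * ACRE_M2)
        x, y = sampler.sample(rng, half_m=side / 2 + 300.0, keepout=sites, min_sep_m=min_sep)
        sites.append((x, y))
        lon, lat = crs.to_lonlat(x, y)
        rows.append({
            "id": f"T{len(rows):06d}", "longitude": float(lon), "latitude": float(lat),
            "date": start + pd.Timedelta(days=int(rng.integers(0, cfg.n_days))),
            "area": area, "burn_type": BurnType.PRESCRIBED.value,
            "event_id": f"E{len(rows):06d}",
        })

    # agricultural burns: inside cropland patches
    if cfg.n_agricultural and not ag_boxes:
        raise ValueError("agricultural burns requested but no cropland patches configured")
    for k in range(cfg.n_agricultural):
        area = float(_lognormal(rng, cfg.ag_area_median_acres, cfg.ag_area_logsd))
        side = math.sqrt(area * ACRE_M2)
        px0, py0, px1, py1 = ag_boxes[int(rng.integers(0, len(ag_boxes)))]
        pad = min(side / 2 + 60.0, (px1 - px0) / 2 - 1, (py1 - py0) / 2 - 1)
        pad = max(pad, 0.0)
        x = rng.uniform(px0 + pad, px1 - pad)
        y = rng.uniform(py0 + pad, py1 - pad)
        lon, lat = crs.to_lonlat(x, y)
        rows.append({
            "id": f"T{len(rows):06d}", "longitude": float(lon), "latitude": float(lat),
            "date": start + pd.Timedelta(days=int(rng.integers(0, cfg.n_days))),
            "area": area, "burn_type": BurnType.AGRICULTURAL.value,
            "event_id": f"E{len(rows):06d}",
        })

    # wildfires: day-indexed chains of detections; the whole chain footprint
    # is kept on background land so typing is decided by duration alone
    wf = cfg.wildfire
    for k in range(cfg.n_wildfire):
        days = int(rng.integers(wf.days[0], wf.days[1] + 1))
        reach = days * wf.step_m[1] + wf.detection_scatter_m + 500.0
        x, y = sampler.sample(rng, half_m=reach, keepout=sites, min_sep_m=min_sep)
        sites.append((x, y))
        day0 = int(rng.integers(0, max(cfg.n_days - days + 1, 1)))
        event = f"E{len(rows):06d}"
        cx, cy = x, y
        for d in range(days):
            if d > 0:
                step = rng.uniform(*wf.step_m)
                theta = rng.uniform(0, 2 * math.pi)
                cx += step * math.cos(theta)
                cy += step * math.sin(theta)
            n_det = int(rng.integers(wf.detections_per_day[0], wf.detections_per_day[1] + 1))
            for _ in range(n_det):
                theta = rng.uniform(0, 2 * math.pi)
                r = rng.uniform(0, wf.detection_scatter_m)
                lon, lat = crs.to_lonlat(cx + r * math.cos(theta), cy + r * math.sin(theta))
                rows.append({
                    "id": f"T{len(rows):06d}", "longitude": float(lon), "latitude": float(lat),
                    "date": start + pd.Timedelta(days=day0 + d),
                    "area": float(_lognormal(rng, wf.area_median_acres, wf.area_logsd)),
                    "burn_type": BurnType.WILDFIRE.value,
                    "event_id": event,
                })

    df = pd.DataFrame(rows, columns=["id", "longitude", "latitude", "date", "area", "burn_type", "event_id"])
    truth = RecordSet(df, Source.TRUTH, {"scenario_seed": cfg.seed})
    return truth, lc


def observe(truth: RecordSet, cfg: ScenarioConfig,
            crs: LocalEquirectangular) -> tuple[RecordSet, RecordSet, dict]:
    """Derive the permit and satellite views of a truth set.

    Returns ``(permit_view, finn_view, links)`` where links maps each truth
    id to the view ids it produced.
    """
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 1])
    obs = cfg.obs
    links: dict[str, dict[str, list[str]]] = {}
    permit_rows: list[dict] = []
    finn_rows: list[dict] = []

    def jitter(lon, lat, sigma_m):
        x, y = crs.to_xy(lon, lat)
        x = float(x) + rng.normal(0.0, sigma_m)
        y = float(y) + rng.normal(0.0, sigma_m)
        lon2, lat2 = crs.to_lonlat(x, y)
        return float(lon2), float(lat2), x, y

    for row in truth.df.itertuples(index=False):
        links[row.id] = {"permit": [], "finn": []}

        # permit view: prescribed and agricultural burns are all permitted
        if row.burn_type in (BurnType.PRESCRIBED.value, BurnType.AGRICULTURAL.value):
            lon, lat, _, _ = jitter(row.longitude, row.latitude, obs.permit_loc_jitter_m)
            j = obs.permit_date_jitter_days
            shift = int(rng.integers(-j, j + 1)) if j > 0 else 0
            pid = f"P{len(permit_rows):06d}"
            permit_rows.append({
                "id": pid, "longitude": lon, "latitude": lat,
                "date": row.date + pd.Timedelta(days=shift),
                "area": float(row.area * np.exp(rng.normal(0.0, obs.permit_area_logsd))),
                "burn_type": BurnType.UNKNOWN.value, "truth_id": row.id,
            })
            links[row.id]["permit"].append(pid)

        # satellite view: size-dependent detection, biased noisy area,
        # possible segmentation into fragments
        p_detect = float(obs.detect_prob(row.area))
        if rng.uniform() >= p_detect:
            continue
        lon, lat, x, y = jitter(row.longitude, row.latitude, obs.finn_loc_jitter_m)
        total = float(row.area * obs.area_bias * np.exp(rng.normal(0.0, obs.area_noise_logsd)))
        n_frag = 1
        if obs.seg_max_fragments > 1 and row.area > obs.seg_area_acres:
            n_frag = 1 + int(rng.integers(0, obs.seg_max_fragments))
        if n_frag == 1:
            frag_areas = [total]
            frag_xy = [(x, y)]
        else:
            w = rng.dirichlet(np.ones(n_frag))
            frag_areas = list(total * w[:-1])
            frag_areas.append(total - sum(frag_areas))  # exact conservation
            radius = math.sqrt(row.area * ACRE_M2) * math.sqrt(2) / 2.0
            frag_xy = []
            for _ in range(n_frag):
                theta = rng.uniform(0, 2 * math.pi)
                r = radius * math.sqrt(rng.uniform())
                frag_xy.append((x + r * math.cos(theta), y + r * math.sin(theta)))
        for a, (fx, fy) in zip(frag_areas, frag_xy):
            flon, flat = crs.to_lonlat(fx, fy)
            fid = f"F{len(finn_rows):06d}"
            finn_rows.append({
                "id": fid, "longitude": float(flon), "latitude": float(flat),
                "date": row.date, "area": float(a),
                "burn_type": BurnType.UNKNOWN.value, "truth_id": row.id,
            })
            links[row.id]["finn"].append(fid)

    cols = ["id", "longitude", "latitude", "date", "area", "burn_type", "truth_id"]
    permit_view = RecordSet(pd.DataFrame(permit_rows, columns=cols), Source.PERMIT,
                            {"scenario_seed": cfg.seed})
    finn_view = RecordSet(pd.DataFrame(finn_rows, columns=cols), Source.FINN,
                          {"scenario_seed": cfg.seed})
    return permit_view, finn_view, links


@dataclass
class SyntheticScenario:
    """A generated truth plus its two observed views."""

    config: ScenarioConfig
    truth: RecordSet
    landcover: LandCoverGrid
    permit_view: RecordSet
    finn_view: RecordSet
    links: dict

    @classmethod
    def simulate(cls, cfg: ScenarioConfig) -> "SyntheticScenario":
        truth, lc = generate_truth(cfg)
        permit_view, finn_view, links = observe(truth, cfg, lc.crs)
        return cls(config=cfg, truth=truth, landcover=lc,
                   permit_view=permit_view, finn_view=finn_view, links=links)

    def true_types(self, view: RecordSet) -> RecordSet:
        """The view's records relabeled with their truth burn types."""
        truth_type = dict(zip(self.truth.df["id"], self.truth.df["burn_type"]))
        df = view.df.copy()
        if "truth_id" not in df.columns:
            raise ValueError("view does not carry truth links")
        df["burn_type"] = [truth_type[t] for t in df["truth_id"]]
        return view.with_df(df)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records(self.truth, outdir / "truth.csv")
        write_records(self.permit_view, outdir / "permits.csv")
        write_records(self.finn_view, outdir / "finn.csv")
        self.landcover.to_ascii(outdir / "landcover.asc")
        link_rows = [
            {"truth_id": t, "view": v, "view_id": vid}
            for t, d in self.links.items() for v, ids in d.items() for vid in ids
        ]
        pd.DataFrame(link_rows, columns=["truth_id", "view", "view_id"]).to_csv(
            outdir / "links.csv", index=False)


def score_classification(result: RecordSet, truth: RecordSet) -> pd.DataFrame:
    """Per-burn-type precision/recall of predicted labels against truth.

    ``result`` and ``truth`` must hold the same record ids.  Returns a
    DataFrame indexed by burn type with columns tp, fp, fn, precision,
    recall (NaN where undefined).
    """
    r = result.df.set_index("id")["burn_type"]
    t = truth.df.set_index("id")["burn_type"]
    if set(r.index) != set(t.index):
        raise ValueError("result and truth record ids do not align")
    t = t.reindex(r.index)
    types = sorted(set(t) | set(r))
    rows = []
    for ty in types:
        tp = int(((r == ty) & (t == ty)).sum())
        fp = int(((r == ty) & (t != ty)).sum())
        fn = int(((r != ty) & (t == ty)).sum())
        rows.append({
            "burn_type": ty, "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        })
    return pd.DataFrame(rows).set_index("burn_type")
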