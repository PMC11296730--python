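"""Spatio-temporal clustering, wildfire flagging, land-cover typing, elbow."""

import numpy as np
import pandas as pd
import pytest

from rxfire import (
    BurnType,
    Source,
    WildfireDetector,
    classify_agricultural,
    detect_wildfires,
    elbow_tune,
    finalize_types,
    haversine_m,
    spatiotemporal_cluster,
)
from rxfire.burntype import ElbowCurve, _knee_index

from conftest import make_records, uniform_grid

DEG_PER_KM_LAT = 1.0 / 111.19492664455873  # exact for the mean-radius sphere


def offset_lat(lat, meters):
    return lat + meters / 1000.0 * DEG_PER_KM_LAT


def brute_force_components(df, d_spatial, d_temporal):
    """O(n^2) oracle: explicit link matrix + breadth-first transitive closure."""
    n = len(df)
    lon = df["longitude"].to_numpy()
    lat = df["latitude"].to_numpy()
    day = pd.to_datetime(df["date"]).map(lambda t: t.toordinal()).to_numpy()
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_m((lon[i], lat[i]), (lon[j], lat[j]))
            dd = abs(day[i] - day[j])
            if (dd == 0 and d <= d_spatial) or (dd == 1 and d <= d_temporal):
                adj[i].append(j)
                adj[j].append(i)
    label = [-1] * n
    comp = 0
    for s in range(n):
        if label[s] >= 0:
            continue
        stack = [s]
        label[s] = comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if label[v] < 0:
                    label[v] = comp
                    stack.append(v)
        comp += 1
    return np.asarray(label)


def assert_same_partition(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    assert len(a) == len(b)
    pairs_a = {(i, j) for i in range(len(a)) for j in range(i + 1, len(a)) if a[i] == a[j]}
    pairs_b = {(i, j) for i in range(len(b)) for j in range(i + 1, len(b)) if b[i] == b[j]}
    assert pairs_a == pairs_b


def random_detections(rng, n, spread_km=6.0, n_days=4):
    rows = []
    for i in range(n):
        lat = 31.0 + rng.uniform(0, spread_km) * DEG_PER_KM_LAT
        lon = -82.0 + rng.uniform(0, spread_km) * DEG_PER_KM_LAT  # slightly anisotropic; fine
        date = pd.Timestamp("2019-02-01") + pd.Timedelta(days=int(rng.integers(0, n_days)))
        rows.append((f"r{i}", lon, lat, date, 10.0))
    return make_records(rows, source=Source.FINN)


class TestClusteringOracle:
    def test_matches_brute_force_closure(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 120))
            rs = random_detections(rng, n)
            labels = WildfireDetector(1000.0, 800.0).fit_predict(rs)
            oracle = brute_force_components(rs.df, 1000.0, 800.0)
            assert_same_partition(labels, oracle)

    def test_order_invariance(self, rng):
        rs = random_detections(rng, 80)
        labels = WildfireDetector(1000.0, 800.0).fit_predict(rs)
        perm = rng.permutation(80)
        shuffled = rs.with_df(rs.df.iloc[perm].reset_index(drop=True))
        labels_p = WildfireDetector(1000.0, 800.0).fit_predict(shuffled)
        # map back to the original order and compare partitions
        inv = np.empty(80, dtype=int)
        inv[perm] = np.arange(80)
        assert_same_partition(labels, labels_p[inv])

    def test_cluster_count_monotone_in_distances(self, rng):
        rs = random_detections(rng, 100)
        counts_s = [WildfireDetector(d, 800.0).fit(rs).n_clusters_ for d in (200, 500, 1000, 2000, 4000)]
        counts_t = [WildfireDetector(1000.0, d).fit(rs).n_clusters_ for d in (200, 500, 1000, 2000, 4000)]
        assert counts_s == sorted(counts_s, reverse=True)
        assert counts_t == sorted(counts_t, reverse=True)


class TestSpatiotemporalCluster:
    def test_three_day_stack_is_one_cluster(self):
        rs = make_records([
            ("a", -82.0, 31.0, "2019-02-01", 5),
            ("b", -82.0, 31.0, "2019-02-02", 5),
            ("c", -82.0, 31.0, "2019-02-03", 5),
        ])
        clusters = spatiotemporal_cluster(rs, 1000.0, 800.0)
        assert len(clusters) == 1
        assert clusters[0].duration_days == 3
        assert clusters[0].member_ids == {"a", "b", "c"}

    def test_same_day_beyond_spatial_distance_stays_split(self):
        rs = make_records([
            ("a", -82.0, 31.0, "2019-02-01", 5),
            ("b", -82.0, offset_lat(31.0, 1200.0), "2019-02-01", 5),
        ])
        assert len(spatiotemporal_cluster(rs, 1000.0, 800.0)) == 2

    def test_chain_links_transitively_across_days(self):
        lat_a = 31.0
        lat_b = offset_lat(lat_a, 700.0)
        lat_c = offset_lat(lat_b, 700.0)  # 1400 m from a
        rs = make_records([
            ("a", -82.0, lat_a, "2019-02-01", 5),
            ("b", -82.0, lat_b, "2019-02-02", 5),
            ("c", -82.0, lat_c, "2019-02-03", 5),
        ])
        clusters = spatiotemporal_cluster(rs, 1000.0, 800.0)
        assert len(clusters) == 1
        assert clusters[0].member_ids == {"a", "b", "c"}


class TestDetectWildfires:
    def _chain(self, step_ab, step_bc):
        lat_a = 31.0
        lat_b = offset_lat(lat_a, step_ab)
        lat_c = offset_lat(lat_b, step_bc)
        return make_records([
            ("a", -82.0, lat_a, "2019-02-01", 5),
            ("b", -82.0, lat_b, "2019-02-02", 5),
            ("c", -82.0, lat_c, "2019-02-03", 5),
        ])

    def test_multi_day_chain_all_flagged(self):
        out = detect_wildfires(self._chain(700.0, 700.0))
        assert set(out.df["burn_type"]) == {BurnType.WILDFIRE.value}

    def test_breaking_first_step_unflags_singleton_end(self):
        out = detect_wildfires(self._chain(900.0, 700.0))
        types = dict(zip(out.df["id"], out.df["burn_type"]))
        assert types["a"] == BurnType.UNKNOWN.value       # 1-day remnant
        assert types["b"] == BurnType.WILDFIRE.value      # 2-day remnant
        assert types["c"] == BurnType.WILDFIRE.value

    def test_breaking_second_step_unflags_other_end(self):
        out = detect_wildfires(self._chain(700.0, 900.0))
        types = dict(zip(out.df["id"], out.df["burn_type"]))
        assert types["a"] == BurnType.WILDFIRE.value
        assert types["b"] == BurnType.WILDFIRE.value
        assert types["c"] == BurnType.UNKNOWN.value

    def test_lone_detection_untouched(self):
        rs = make_records([("a", -82.0, 31.0, "2019-02-01", 5)])
        out = detect_wildfires(rs)
        assert out.df["burn_type"].iloc[0] == BurnType.UNKNOWN.value

    def test_same_day_pair_is_single_day_cluster(self):
        rs = make_records([
            ("a", -82.0, 31.0, "2019-02-01", 5),
            ("b", -82.0, offset_lat(31.0, 500.0), "2019-02-01", 5),
        ])
        out = detect_wildfires(rs)
        assert set(out.df["burn_type"]) == {BurnType.UNKNOWN.value}

    def test_agricultural_records_do_not_seed_chains(self):
        rs = make_records([
            ("a", -82.0, 31.0, "2019-02-01", 5, BurnType.AGRICULTURAL.value),
            ("b", -82.0, 31.0, "2019-02-02", 5),
        ])
        out = detect_wildfires(rs)
        types = dict(zip(out.df["id"], out.df["burn_type"]))
        assert types["a"] == BurnType.AGRICULTURAL.value
        assert types["b"] == BurnType.UNKNOWN.value


class TestClassifyAgricultural:
    def test_cropland_flagged_agricultural(self):
        rs = make_records([("a", -82.0, 31.0, "2019-02-01", 10)])
        out = classify_agricultural(rs, {2019: uniform_grid(82)})
        assert out.df["burn_type"].iloc[0] == BurnType.AGRICULTURAL.value

    def test_barren_flagged_invalid(self):
        rs = make_records([("a", -82.0, 31.0, "2019-02-01", 10)])
        out = classify_agricultural(rs, {2019: uniform_grid(31)})
        assert out.df["burn_type"].iloc[0] == BurnType.INVALID.value

    def test_forest_left_unknown(self):
        rs = make_records([("a", -82.0, 31.0, "2019-02-01", 10)])
        out = classify_agricultural(rs, {2019: uniform_grid(42)})
        assert out.df["burn_type"].iloc[0] == BurnType.UNKNOWN.value

    def test_unresolvable_location_flagged_not_typed(self):
        rs = make_records([("far", -70.0, 40.0, "2019-02-01", 10)])
        out = classify_agricultural(rs, {2019: uniform_grid(82)})
        assert out.df["burn_type"].iloc[0] == BurnType.UNKNOWN.value
        assert out.provenance["landcover_unresolved"] == ["far"]


class TestFinalizeTypes:
    def test_remainder_becomes_prescribed_and_invalid_dropped(self):
        rs = make_records([
            ("u", -82.0, 31.0, "2019-02-01", 5, BurnType.UNKNOWN.value),
            ("w", -82.0, 31.0, "2019-02-01", 5, BurnType.WILDFIRE.value),
            ("i", -82.0, 31.0, "2019-02-01", 5, BurnType.INVALID.value),
            ("g", -82.0, 31.0, "2019-02-01", 5, BurnType.AGRICULTURAL.value),
        ])
        out = finalize_types(rs)
        types = dict(zip(out.df["id"], out.df["burn_type"]))
        assert types == {"u": BurnType.PRESCRIBED.value, "w": BurnType.WILDFIRE.value,
                         "g": BurnType.AGRICULTURAL.value}
        # conservation: |in| = |out| + dropped INVALID
        assert len(rs) == len(out) + out.provenance["dropped_invalid"]


class TestElbow:
    def test_worked_example_knee(self):
        idx, _ = _knee_index(np.array([200.0, 400, 600, 800, 1000]),
                             np.array([100.0, 100, 40, 38, 37]))
        assert [200.0, 400, 600, 800, 1000][idx] == 600

    def test_linear_counts_have_no_knee(self):
        with pytest.raises(ValueError, match="no knee"):
            _knee_index(np.array([1.0, 2, 3, 4, 5]), np.array([50.0, 40, 30, 20, 10]))

    def test_constant_counts_have_no_knee(self):
        with pytest.raises(ValueError, match="no knee"):
            _knee_index(np.array([1.0, 2, 3, 4]), np.array([7.0, 7, 7, 7]))

    def test_too_few_candidates_error(self, rng):
        rs = random_detections(rng, 10)
        with pytest.raises(ValueError, match="at least 4"):
            elbow_tune(rs, [200, 400, 600], mode="spatial")

    def _chained_records(self, rng, n_chains=40, steps=(650.0, 790.0)):
        """Wildfire-like 3-day chains with consecutive-day steps in `steps`,
        origins >= 5 km apart: the true linkage scale is the step range."""
        rows = []
        for c in range(n_chains):
            x0 = (c % 8) * 5000.0
            y0 = (c // 8) * 5000.0
            x, y = x0, y0
            for d in range(3):
                if d > 0:
                    step = rng.uniform(*steps)
                    theta = rng.uniform(0, 2 * np.pi)
                    x += step * np.cos(theta)
                    y += step * np.sin(theta)
                lat = 31.0 + y / 1000.0 * DEG_PER_KM_LAT
                lon = -82.0 + (x / 1000.0 * DEG_PER_KM_LAT) / np.cos(np.radians(31.0))
                rows.append((f"c{c}d{d}", lon, lat, pd.Timestamp("2019-02-01") + pd.Timedelta(days=d), 5.0))
        return make_records(rows, source=Source.FINN)

    def test_recovers_true_linkage_scale(self, rng):
        """Chains built with steps in (650, 790) m: the knee of the temporal
        clustering curve lands within one candidate step of 800 m."""
        rs = self._chained_records(rng)
        candidates = [200.0 * k for k in range(1, 11)]
        curve = elbow_tune(rs, candidates, mode="temporal")
        assert abs(curve.knee - 800.0) <= 200.0
        assert curve.knee in curve.distances

    def test_joint_mode_accepts_distance_pairs(self, rng):
        rs = self._chained_records(rng)
        cands = [(d, d * 0.8) for d in (250.0, 500.0, 750.0, 1000.0, 1250.0, 1500.0)]
        curve = elbow_tune(rs, cands, mode="joint")
        assert curve.knee in cands
        assert len(curve.counts) == len(cands)
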