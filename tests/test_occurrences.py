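"""Cleaning rules, spatial thinning, outlier removal — against direct oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from emusdm import CleaningRules, clean, remove_outliers, thin
from emusdm.distances import EARTH_RADIUS_KM, haversine_km, pairwise_dist_km


def make_records(**overrides) -> pd.DataFrame:
    base = dict(
        lon=[10.0, 20.0, 30.0],
        lat=[10.0, 20.0, 30.0],
        year=[2000.0, 2005.0, 2010.0],
        coord_uncertainty_m=[100.0, 200.0, 300.0],
        is_fossil=[False] * 3,
        is_absence_record=[False] * 3,
        source=["t"] * 3,
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestClean:
    def test_valid_records_pass_unchanged(self):
        df = make_records()
        kept, report = clean(df, CleaningRules(outlier_radius_km=30.0))
        assert len(kept) == 3
        assert all(v == 0 for v in report.removed_by_rule.values())

    @pytest.mark.parametrize(
        "column,bad_value,rule",
        [
            ("coord_uncertainty_m", 6000.0, "uncertainty"),
            ("year", np.nan, "missing_year"),
            ("year", 1950.0, "early_year"),
            ("is_fossil", True, "fossil"),
            ("is_absence_record", True, "absence"),
        ],
    )
    def test_each_rule_fires(self, column, bad_value, rule):
        df = make_records()
        df.loc[1, column] = bad_value
        kept, report = clean(df)
        assert len(kept) == 2
        assert report.removed_by_rule[rule] == 1

    def test_uncertainty_exactly_5km_kept(self):
        df = make_records(coord_uncertainty_m=[5000.0, 100.0, 100.0])
        kept, _ = clean(df)
        assert len(kept) == 3  # rule is strictly greater than 5 km

    def test_missing_uncertainty_kept_by_default_dropped_when_strict(self):
        df = make_records(coord_uncertainty_m=[np.nan, 100.0, 100.0])
        kept, _ = clean(df)
        assert len(kept) == 3
        kept, report = clean(df, CleaningRules(drop_missing_uncertainty=True))
        assert len(kept) == 2
        assert report.removed_by_rule["uncertainty"] == 1

    def test_duplicates_collapse_to_one(self):
        df = make_records(lon=[10.0, 10.0, 30.0], lat=[10.0, 10.0, 30.0])
        kept, report = clean(df)
        assert len(kept) == 2
        assert report.removed_by_rule["duplicate"] == 1

    def test_city_exclusion(self):
        df = make_records()
        kept, report = clean(df, city_points=np.array([[10.0, 14.0]]))
        # first record is 4 km from the city (< 10 km rule)
        assert len(kept) == 2
        assert report.removed_by_rule["city"] == 1

    def test_region_mask_exclusion(self):
        rules = CleaningRules(excluded_region_masks=(box(25.0, 25.0, 35.0, 35.0),))
        kept, report = clean(make_records(), rules)
        assert len(kept) == 2
        assert report.removed_by_rule["region"] == 1

    def test_outlier_removed_cluster_kept(self):
        rng = np.random.default_rng(0)
        cluster = rng.uniform(0, 20, size=(10, 2))
        pts = np.vstack([cluster, [200.0, 200.0]])
        df = make_records(
            lon=pts[:, 0], lat=pts[:, 1],
            year=[2000.0] * 11, coord_uncertainty_m=[100.0] * 11,
            is_fossil=[False] * 11, is_absence_record=[False] * 11, source=["t"] * 11,
        )
        kept, report = clean(df)
        assert len(kept) == 10
        assert report.removed_by_rule["outlier"] == 1

    def test_record_violating_multiple_rules_counted_per_rule_removed_once(self):
        df = make_records()
        df.loc[1, "coord_uncertainty_m"] = 9000.0
        df.loc[1, "is_fossil"] = True
        kept, report = clean(df)
        assert len(kept) == 2
        assert report.removed_by_rule["uncertainty"] == 1
        assert report.removed_by_rule["fossil"] == 1

    def test_idempotent(self, small_presences):
        once, _ = clean(small_presences)
        twice, report = clean(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in report.removed_by_rule.values())

    def test_permutation_invariant(self, small_presences):
        rules = CleaningRules()
        a, _ = clean(small_presences, rules)
        shuffled = small_presences.sample(frac=1.0, random_state=5)
        b, _ = clean(shuffled, rules)
        key = ["lon", "lat"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_empty_input_rejected_all_removed_flagged(self):
        with pytest.raises(ValueError):
            clean(pd.DataFrame(columns=make_records().columns))
        df = make_records(is_fossil=[True, True, True])
        kept, report = clean(df)
        assert len(kept) == 0 and report.all_removed


def greedy_thin_oracle(xy: np.ndarray, order: np.ndarray, min_dist: float) -> list[int]:
    """Independent greedy re-implementation (naive loops)."""
    accepted: list[int] = []
    for i in order:
        ok = True
        for j in accepted:
            if np.hypot(*(xy[i] - xy[j])) < min_dist:
                ok = False
                break
        if ok:
            accepted.append(int(i))
    return sorted(accepted)


class TestThin:
    def test_already_sparse_all_retained(self):
        xs, ys = np.meshgrid(np.arange(5) * 50.0, np.arange(5) * 50.0)
        df = pd.DataFrame({"lon": xs.ravel(), "lat": ys.ravel()})
        out = thin(df, 30.0, seed=0)
        assert len(out) == 25

    def test_tight_cluster_collapses_to_singleton(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, size=(20, 2))  # all within a 5-km disc
        df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
        assert len(thin(df, 30.0, seed=2)) == 1

    def test_matches_seeded_greedy_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 300, size=(200, 2))
        df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
        seed = 17
        out = thin(df, 30.0, seed=seed)
        order = np.random.default_rng(seed).permutation(len(df))
        expected = greedy_thin_oracle(pts, order, 30.0)
        assert list(out.index) == list(range(len(expected)))
        np.testing.assert_allclose(out[["lon", "lat"]].to_numpy(), pts[expected])

    def test_pairwise_distances_respect_minimum_and_idempotent(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 200, size=(150, 2))
        df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
        out = thin(df, 30.0, seed=9)
        d = pairwise_dist_km(out[["lon", "lat"]].to_numpy(), out[["lon", "lat"]].to_numpy())
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 30.0
        again = thin(out, 30.0, seed=123)  # any seed: constraint already met
        assert len(again) == len(out)

    def test_single_point_passes_through(self):
        df = pd.DataFrame({"lon": [1.0], "lat": [2.0]})
        assert len(thin(df, 30.0, seed=0)) == 1


class TestRemoveOutliers:
    def test_close_pair_kept(self):
        df = pd.DataFrame({"lon": [0.0, 10.0], "lat": [0.0, 0.0]})
        assert len(remove_outliers(df, 30.0)) == 2

    def test_far_point_dropped(self):
        pts = np.vstack([np.random.default_rng(5).uniform(0, 10, (10, 2)), [500.0, 0.0]])
        df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
        out = remove_outliers(df, 30.0)
        assert len(out) == 10
        assert 500.0 not in out["lon"].to_numpy()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 150, size=(60, 2))
        df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
        out = remove_outliers(df, 25.0)
        keep = []
        for i in range(len(pts)):  # O(n^2) oracle
            dmin = min(
                np.hypot(*(pts[i] - pts[j])) for j in range(len(pts)) if j != i
            )
            if dmin <= 25.0:
                keep.append(i)
        np.testing.assert_allclose(out[["lon", "lat"]].to_numpy(), pts[keep])

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(pd.DataFrame({"lon": [0.0], "lat": [0.0]}), 30.0)


class TestDistances:
    def test_haversine_against_direct_formula(self):
        rng = np.random.default_rng(7)
        lon1, lat1 = rng.uniform(-180, 180, 50), rng.uniform(-89, 89, 50)
        lon2, lat2 = rng.uniform(-180, 180, 50), rng.uniform(-89, 89, 50)
        # spherical law of cosines as the independent formula
        p1, p2 = np.radians(lat1), np.radians(lat2)
        dl = np.radians(lon2 - lon1)
        cosang = np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
        expected = EARTH_RADIUS_KM * np.arccos(cosang)
        got = haversine_km(lon1, lat1, lon2, lat2)
        np.testing.assert_allclose(got, expected, atol=1e-3)  # within 1 m

    def test_quarter_meridian(self):
        # pole-to-equator along a meridian = 1/4 of the great circle
        d = haversine_km(0.0, 0.0, 0.0, 90.0)
        np.testing.assert_allclose(d, np.pi * EARTH_RADIUS_KM / 2, rtol=1e-12)
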