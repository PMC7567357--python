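"""Temporal lag metrics, permutation null and classification rules."""
import numpy as np
import pandas as pd
import pytest

from covisit import (AnalysisConfig, LagSet, PermutationImpossibleError,
                     classify_model2, classify_model3, null3_distribution,
                     observed_lags, permute_occurrences, spatial_null_lags)
from covisit.temporal import pair_rng
from conftest import make_stations, make_visits

from _oracles import (brute_observed_lags, brute_spatial_null_lags,
                      random_station_table, random_visits)


@pytest.fixture
def cfg():
    return AnalysisConfig(seed=3, iterations=60, bootstrap_resamples=300)


class TestObservedLags:
    def test_first_later_visit_only(self, cfg):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("A", "sp2", "2019-05-01 02:00:00"),
            ("A", "sp2", "2019-05-01 05:00:00"),
        ])
        lags = observed_lags(v, "sp1", "sp2", cfg).lags
        assert lags.tolist() == [2.0]

    def test_lag_beyond_cap_not_emitted(self, cfg):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("A", "sp2", "2019-05-02 16:00:00"),  # 40 h later
        ])
        assert observed_lags(v, "sp1", "sp2", cfg).lags.size == 0

    def test_within_station_only(self, cfg):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("B", "sp2", "2019-05-01 01:00:00"),
        ])
        assert observed_lags(v, "sp1", "sp2", cfg).lags.size == 0

    def test_simultaneous_visits_skipped_by_default(self, cfg):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("A", "sp2", "2019-05-01 00:00:00"),
            ("A", "sp2", "2019-05-01 03:00:00"),
        ])
        assert observed_lags(v, "sp1", "sp2", cfg).lags.tolist() == [3.0]
        with_zero = cfg.replace(include_zero_lag=True)
        assert observed_lags(v, "sp1", "sp2", with_zero).lags.tolist() == [0.0]

    def test_many_first_visits_may_share_one_second_visit(self, cfg):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("A", "sp1", "2019-05-01 01:00:00"),
            ("A", "sp2", "2019-05-01 02:00:00"),
        ])
        assert sorted(observed_lags(v, "sp1", "sp2", cfg).lags) == [1.0, 2.0]

    def test_matches_brute_force_on_random_data(self, cfg, rng):
        for _ in range(200):
            v = random_visits(rng)
            species = v["species"].unique()
            if len(species) < 2:
                continue
            sp1, sp2 = species[:2]
            got = np.sort(observed_lags(v, sp1, sp2, cfg).lags)
            want = brute_observed_lags(v, sp1, sp2, cfg.max_lag_hours)
            assert got.tolist() == pytest.approx(want, abs=1e-9)


class TestSpatialNullLags:
    def test_distance_threshold_strict(self, cfg, four_stations):
        # A-B = 150 m eligible at 100 m; A-C = 80 m not eligible
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("B", "sp2", "2019-05-01 03:00:00"),
            ("C", "sp2", "2019-05-01 01:00:00"),
        ])
        lags = spatial_null_lags(v, "sp1", "sp2", four_stations, cfg)
        assert lags.lags.tolist() == [3.0]

    def test_same_station_never_contributes(self, cfg, four_stations):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("A", "sp2", "2019-05-01 01:00:00"),
        ])
        assert spatial_null_lags(v, "sp1", "sp2", four_stations,
                                 cfg).lags.size == 0

    def test_no_eligible_pair_gives_empty(self, cfg):
        close = make_stations({"A": (0, 0), "B": (50, 0)})
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("B", "sp2", "2019-05-01 01:00:00"),
        ])
        assert spatial_null_lags(v, "sp1", "sp2", close, cfg).lags.size == 0

    def test_matches_brute_force_on_random_data(self, cfg, rng):
        for _ in range(40):
            v = random_visits(rng, n_max=120)
            stations = random_station_table(rng, sorted(v["station_id"].unique()))
            species = v["species"].unique()
            if len(species) < 2:
                continue
            sp1, sp2 = species[:2]
            got = np.sort(spatial_null_lags(v, sp1, sp2, stations, cfg).lags)
            want = brute_spatial_null_lags(v, sp1, sp2, stations,
                                           cfg.min_distance_m,
                                           cfg.max_lag_hours)
            assert got.tolist() == pytest.approx(want, abs=1e-9)


class TestClassifyModel2:
    def test_below_min_obs_is_ineligible(self, cfg):
        obs = LagSet("a", "b", np.array([1.0, 2.0, 3.0]), "observed")
        exp = LagSet("a", "b", np.linspace(1, 30, 50), "spatial_null")
        res = classify_model2(obs, exp, cfg)
        assert res.classification == "ineligible"
        assert res.n_obs == 3

    def test_identical_multisets_classified_none(self, cfg):
        lags = np.linspace(0.5, 30, 40)
        obs = LagSet("a", "b", lags, "observed")
        exp = LagSet("a", "b", lags.copy(), "spatial_null")
        res = classify_model2(obs, exp, cfg)
        assert res.classification == "none"
        assert res.lower_95 <= res.lower_90 <= res.upper_90 <= res.upper_95
        assert res.omtd == pytest.approx(lags.mean())

    def test_extreme_omtd_classified(self, cfg):
        exp = LagSet("a", "b", np.linspace(10, 30, 60), "spatial_null")
        low = LagSet("a", "b", np.full(10, 1.0), "observed")
        high = LagSet("a", "b", np.full(10, 35.0), "observed")
        assert classify_model2(low, exp, cfg).classification == "attraction"
        assert classify_model2(high, exp, cfg).classification == "aversion"


class TestPermutation:
    def test_two_stations_deterministically_swap(self, rng):
        stations = make_stations({"A": (0, 0), "B": (10, 0)})
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("B", "sp2", "2019-05-01 01:00:00"),
        ])
        out = permute_occurrences(v, stations, rng)
        assert list(out["station_id"]) == ["B", "A"]

    def test_single_station_impossible(self, rng):
        stations = make_stations({"A": (0, 0)})
        v = make_visits([("A", "sp1", "2019-05-01 00:00:00")])
        with pytest.raises(PermutationImpossibleError):
            permute_occurrences(v, stations, rng)

    def test_preserves_counts_timestamps_and_moves_everyone(self, rng):
        for _ in range(100):
            v = random_visits(rng, n_max=80)
            ids = sorted(v["station_id"].unique())
            if len(ids) < 2:
                continue
            stations = random_station_table(rng, ids)
            out = permute_occurrences(v, stations, rng)
            assert (out["station_id"] != v["station_id"]).all()
            for col in ("species", "start_time", "interaction"):
                assert out[col].equals(v[col])
            before = v.groupby("species").size()
            after = out.groupby("species").size()
            assert before.equals(after)

    def test_respect_activity_restricts_targets(self, rng):
        stations = make_stations({"A": (0, 0), "B": (10, 0), "C": (20, 0)})
        stations.loc[stations["station_id"] == "B", "active_end"] = \
            pd.Timestamp("2019-05-02")
        v = make_visits([("A", "sp1", "2019-06-10 00:00:00")] * 20)
        out = permute_occurrences(v, stations, rng, respect_activity=True)
        assert set(out["station_id"]) == {"C"}


class TestNull3:
    def test_deterministic_under_seed(self, cfg, four_stations):
        v = make_visits([
            ("A", "sp1", "2019-05-01 00:00:00"),
            ("B", "sp2", "2019-05-01 02:00:00"),
            ("C", "sp1", "2019-05-02 00:00:00"),
            ("D", "sp2", "2019-05-02 05:00:00"),
        ])
        m1 = null3_distribution(v, "sp1", "sp2", four_stations, cfg)
        m2 = null3_distribution(v, "sp1", "sp2", four_stations, cfg)
        assert np.array_equal(m1, m2, equal_nan=True)

    def test_single_iteration_equals_permuted_observed_mean(self, four_stations):
        cfg1 = AnalysisConfig(seed=5, iterations=1)
        # sp1 rows before sp2 rows so the iteration's station draws line
        # up with a standalone permutation of the same table
        v = make_visits(
            [("A", "sp1", f"2019-05-0{d} 00:00:00") for d in (1, 2, 3)]
            + [("B", "sp2", f"2019-05-0{d} 02:00:00") for d in (1, 2, 3)])
        means = null3_distribution(v, "sp1", "sp2", four_stations, cfg1)
        rng = pair_rng(5, "sp1", "sp2")
        permuted = permute_occurrences(v, four_stations, rng)
        want = observed_lags(permuted, "sp1", "sp2", cfg1).lags
        if want.size:
            assert means[0] == pytest.approx(want.mean())
        else:
            assert np.isnan(means[0])

    def test_classify_bounds_and_rules(self, cfg):
        means = np.linspace(10, 20, 200)
        low = classify_model3(5.0, 10, means, cfg)
        mid = classify_model3(15.0, 10, means, cfg)
        high = classify_model3(25.0, 10, means, cfg)
        assert low.classification == "attraction"
        assert mid.classification == "none"
        assert high.classification == "aversion"
        assert low.lower_95 <= low.lower_90 <= low.upper_90 <= low.upper_95

    def test_nan_iterations_excluded_and_counted(self, cfg):
        means = np.r_[np.full(10, np.nan), np.linspace(10, 20, 50)]
        res = classify_model3(15.0, 10, means, cfg)
        assert res.n_exp == 50
        few = np.r_[np.full(58, np.nan), [12.0, 13.0]]
        assert classify_model3(15.0, 10, few, cfg).classification == "ineligible"


class TestPairStreams:
    def test_pair_stream_stable_and_distinct(self):
        a1 = pair_rng(9, "fox", "boar").integers(0, 1 << 30, 5)
        a2 = pair_rng(9, "fox", "boar").integers(0, 1 << 30, 5)
        b = pair_rng(9, "boar", "fox").integers(0, 1 << 30, 5)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)
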