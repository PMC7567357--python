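"""The synthetic detection-stream generator."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from covisit import (InteractionKernel, ScenarioConfig, SpeciesProfile,
                     ValidationError, cluster_visits, ground_truth,
                     load_scenario, no_interaction_scenario, simulate)
from covisit.simulate import circadian_density


def _event_counts(detections, burst):
    per = detections.groupby(["station_id", "species"]).size() / burst
    return per


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesProfile("a", baseline_rate=-1)

    def test_zero_effect_kernel_rejected(self):
        with pytest.raises(ValidationError):
            InteractionKernel("a", "b", effect=0, duration_hours=1)

    def test_cyclic_kernel_graph_rejected(self):
        sp = (SpeciesProfile("a", 1.0), SpeciesProfile("b", 1.0))
        kernels = (InteractionKernel("a", "b", 2, 1),
                   InteractionKernel("b", "a", 2, 1))
        with pytest.raises(ValidationError, match="cyclic"):
            ScenarioConfig(species=sp, kernels=kernels)

    def test_unknown_kernel_species_rejected(self):
        sp = (SpeciesProfile("a", 1.0),)
        with pytest.raises(ValidationError):
            ScenarioConfig(species=sp,
                           kernels=(InteractionKernel("a", "zz", 2, 1),))


class TestPoissonCounts:
    def test_counts_match_rate_times_days(self):
        # flat circadian, no kernels: counts are plain Poisson
        scen = no_interaction_scenario(n_species=1, n_stations=100,
                                       season_days=30, baseline_rate=1.0,
                                       seed=10)
        det, _, _ = simulate(scen)
        counts = _event_counts(det, scen.photo_burst)
        counts = counts.reindex(
            pd.MultiIndex.from_product(
                [[f"P{i + 1:03d}" for i in range(100)], ["sp1"]]),
            fill_value=0)
        mean = counts.mean()
        expected = 30.0
        mc_sd = np.sqrt(expected / 100)
        assert abs(mean - expected) < 3 * mc_sd
        # index of dispersion ~ 1 for Poisson
        assert 0.6 < counts.var() / counts.mean() < 1.5

    def test_photo_bursts_expand_each_event(self):
        scen = no_interaction_scenario(n_stations=5, season_days=10, seed=2)
        det, _, _ = simulate(scen)
        assert len(det) % scen.photo_burst == 0
        v = cluster_visits(det, 5)
        assert v["n_records"].sum() == len(det)


class TestCircadian:
    def test_density_integrates_to_one(self):
        sp = SpeciesProfile("a", 1.0, circadian=((22.0, 2.0, 0.7),
                                                 (6.0, 4.0, 0.3)))
        h = np.linspace(0, 24, 100001)
        area = np.trapezoid(circadian_density(sp, h), h)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_simulated_rhythm_matches_density(self):
        # chi-square goodness of fit of event hours against the density
        sp = SpeciesProfile("sp1", 4.0, circadian=((22.0, 2.0, 1.0),))
        scen = ScenarioConfig(species=(sp,), n_stations=50, season_days=60,
                              photo_burst=1, seed=5)
        det, _, _ = simulate(scen)
        hours = (det["timestamp"].dt.hour
                 + det["timestamp"].dt.minute / 60.0).to_numpy()
        edges = np.arange(0, 25, 1.0)
        observed, _ = np.histogram(hours, bins=edges)
        centers = edges[:-1] + 0.5
        probs = circadian_density(sp, centers)
        probs = probs / probs.sum()
        stat, p = scipy.stats.chisquare(observed, observed.sum() * probs)
        assert observed.sum() > 10000
        assert p > 0.01

    def test_night_peak_shifts_events(self):
        nocturnal = SpeciesProfile("sp1", 2.0, circadian=((2.0, 3.0, 1.0),))
        scen = ScenarioConfig(species=(nocturnal,), n_stations=20,
                              season_days=30, photo_burst=1, seed=6)
        det, _, _ = simulate(scen)
        hours = det["timestamp"].dt.hour
        night = ((hours < 6) | (hours >= 22)).mean()
        assert night > 0.6


class TestKernels:
    def test_unit_effect_kernel_identical_to_no_kernel(self):
        sp = (SpeciesProfile("a", 1.0), SpeciesProfile("b", 1.0))
        base = ScenarioConfig(species=sp, n_stations=10, season_days=20,
                              seed=8)
        with_null_kernel = base.replace(
            kernels=(InteractionKernel("a", "b", 1.0, 2.0),))
        det0, st0, _ = simulate(base)
        det1, st1, _ = simulate(with_null_kernel)
        pd.testing.assert_frame_equal(det0, det1)
        pd.testing.assert_frame_equal(st0, st1)

    def test_excitation_shortens_observed_lags(self):
        sp = (SpeciesProfile("a", 1.0), SpeciesProfile("b", 1.0))
        base = ScenarioConfig(species=sp, n_stations=20, season_days=60,
                              photo_burst=1, seed=9)
        excited = base.replace(kernels=(InteractionKernel("a", "b", 10, 2),))
        def mean_lag(scen):
            det, _, _ = simulate(scen)
            lags = []
            for _, grp in det.groupby("station_id"):
                ta = grp.loc[grp["species"] == "a", "timestamp"].to_numpy()
                tb = np.sort(grp.loc[grp["species"] == "b",
                                     "timestamp"].to_numpy())
                for t in ta:
                    later = tb[tb > t]
                    if later.size:
                        lags.append((later[0] - t) / np.timedelta64(1, "h"))
            return np.mean(lags)
        assert mean_lag(excited) < mean_lag(base)

    def test_kernel_locality_other_stations_untouched(self):
        # an extreme kernel at every station must not change species a's
        # own stream, and species b changes only where a is present
        a = SpeciesProfile("a", 0.0)  # a never visits
        b = SpeciesProfile("b", 1.0)
        base = ScenarioConfig(species=(a, b), n_stations=10, season_days=30,
                              seed=11)
        kern = base.replace(kernels=(InteractionKernel("a", "b", 50, 5),))
        det0, _, _ = simulate(base)
        det1, _, _ = simulate(kern)
        # with no trigger events anywhere the kernel can never activate
        pd.testing.assert_frame_equal(det0, det1)


class TestDeterminismAndTruth:
    def test_identical_seed_byte_identical_output(self, tmp_path):
        scen = no_interaction_scenario(seed=13)
        for run in ("x", "y"):
            det, st, truth = simulate(scen)
            det.to_csv(tmp_path / f"d_{run}.csv", index=False)
            st.to_csv(tmp_path / f"s_{run}.csv", index=False)
            truth.to_csv(tmp_path / f"t_{run}.csv", index=False)
        for name in ("d", "s", "t"):
            assert (tmp_path / f"{name}_x.csv").read_bytes() == \
                (tmp_path / f"{name}_y.csv").read_bytes()

    def test_ground_truth_labels(self):
        sp = (SpeciesProfile("a", 1.0), SpeciesProfile("b", 1.0))
        excite = ScenarioConfig(species=sp,
                                kernels=(InteractionKernel("a", "b", 10, 2),))
        t = ground_truth(excite).set_index(["sp_first", "sp_second"])
        assert t.loc[("a", "b"), "truth_temporal"] == "attraction"
        assert t.loc[("b", "a"), "truth_temporal"] == "none"
        anti = ScenarioConfig(species=sp, station_effect_sigma=1.0,
                              effect_correlation=("a", "b", -0.9))
        t2 = ground_truth(anti).set_index(["sp_first", "sp_second"])
        assert t2.loc[("a", "b"), "truth_couse"] == "avoidance"
        none = ScenarioConfig(species=sp)
        t3 = ground_truth(none)
        assert (t3["truth_temporal"] == "none").all()
        assert (t3["truth_couse"] == "none").all()

    def test_scenario_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "scen.yaml"
        path.write_text(
            "species:\n"
            "  - {name: fox, baseline_rate: 0.4, "
            "functional_role: legitimate_disperser}\n"
            "  - {name: cow, baseline_rate: 0.8, "
            "functional_role: seed_predator}\n"
            "kernels:\n"
            "  - {trigger: cow, responder: fox, effect: 5, "
            "duration_hours: 2}\n"
            "n_stations: 12\nseason_days: 45\nseed: 3\n")
        scen = load_scenario(path)
        assert scen.n_stations == 12
        assert scen.kernels[0].trigger == "cow"
        det, st, truth = simulate(scen)
        assert set(det["species"]) <= {"fox", "cow"}
        assert len(st) == 12
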