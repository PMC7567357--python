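"""Replicated simulation studies: type-I error, power, recovery.

These drive the full pipeline (simulate -> cluster photos into visits ->
null model) over many replicate synthetic surveys with known ground
truth, and report detection fractions. They are what the package's own
validation and the worked examples run; replicate counts are arguments
so small smoke runs and full studies share one code path.

Study conditions follow the canned scenarios in :mod:`covisit.simulate`:
20 stations in a 1 km square, 60-day seasons, 0.5 visits/station/day
baseline, excitation x10 for 2 h for the temporal power study, and
sigma = 1, rho = -0.9 anticorrelated station effects for the spatial
co-use recovery study.
"""
from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .couse import couse_test
from .events import cluster_visits
from .simulate import (couse_scenario, excitation_scenario,
                       no_interaction_scenario)
from .temporal import (classify_model3, null3_distribution, observed_lags,
                       temporal_test)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def _simulate_visits(scenario, config):
    from .simulate import simulate
    detections, stations, _ = simulate(scenario)
    visits = cluster_visits(detections, config.window_minutes)
    return visits, stations


def model3_type1_study(n_replicates: int = 200, iterations: int = 200,
                       seed: int = 0, n_stations: int = 20,
                       season_days: float = 60.0,
                       baseline_rate: float = 0.5) -> dict:
    """Type-I error of the permutation null under no interaction.

    Each replicate is an independent homogeneous-Poisson two-species
    survey; a detection is an attraction or aversion call for the
    ordered pair (sp1, sp2). The detection fraction should sit near the
    nominal 5% of a two-sided 95% interval.
    """
    seeds = _child_seeds(seed, n_replicates)
    detections = 0
    eligible = 0
    for i in range(n_replicates):
        scen = no_interaction_scenario(n_stations=n_stations,
                                       season_days=season_days,
                                       baseline_rate=baseline_rate,
                                       seed=int(seeds[i]))
        config = AnalysisConfig(iterations=iterations, seed=int(seeds[i]))
        visits, stations = _simulate_visits(scen, config)
        obs = observed_lags(visits, "sp1", "sp2", config)
        means = null3_distribution(visits, "sp1", "sp2", stations, config)
        omtd = float(obs.lags.mean()) if obs.lags.size else float("nan")
        res = classify_model3(omtd, obs.lags.size, means, config, "sp1", "sp2")
        if res.classification in ("attraction", "aversion"):
            detections += 1
        if res.classification != "ineligible":
            eligible += 1
    return {"rate": detections / n_replicates, "detections": detections,
            "eligible": eligible, "n_replicates": n_replicates}


def temporal_power_study(n_replicates: int = 100, iterations: int = 200,
                         seed: int = 0, effect: float = 10.0,
                         duration_hours: float = 2.0, n_stations: int = 20,
                         season_days: float = 60.0,
                         baseline_rate: float = 0.5) -> dict:
    """Power of both temporal nulls under a known excitation kernel.

    Returns attraction-detection fractions for the true (trigger,
    responder) ordered pair and for the reverse pair, for the
    station-pair null ("model2") and the permutation null ("model3").
    """
    seeds = _child_seeds(seed, n_replicates)
    hits = {("2", "fwd"): 0, ("2", "rev"): 0, ("3", "fwd"): 0, ("3", "rev"): 0}
    for i in range(n_replicates):
        scen = excitation_scenario(effect=effect,
                                   duration_hours=duration_hours,
                                   n_stations=n_stations,
                                   season_days=season_days,
                                   baseline_rate=baseline_rate,
                                   seed=int(seeds[i]))
        config = AnalysisConfig(iterations=iterations, seed=int(seeds[i]))
        visits, stations = _simulate_visits(scen, config)
        for model in ("2", "3"):
            for tag, pair in (("fwd", ("sp1", "sp2")),
                              ("rev", ("sp2", "sp1"))):
                res = temporal_test(visits, pair[0], pair[1], stations,
                                    config, model)
                if res.classification == "attraction":
                    hits[(model, tag)] += 1
    return {
        "model2_power": hits[("2", "fwd")] / n_replicates,
        "model2_reverse_rate": hits[("2", "rev")] / n_replicates,
        "model3_power": hits[("3", "fwd")] / n_replicates,
        "model3_reverse_rate": hits[("3", "rev")] / n_replicates,
        "n_replicates": n_replicates,
    }


def couse_recovery_study(n_replicates: int = 100, seed: int = 0,
                         rho: float = -0.9, sigma: float = 1.0,
                         n_stations: int = 20,
                         season_days: float = 60.0) -> dict:
    """Spatial co-use recovery under (anti)correlated station effects.

    With ``rho`` and ``sigma`` non-zero the true label for (sp1 | sp2)
    is avoidance (rho < 0) or attraction (rho > 0); with sigma = 0 the
    scenario degenerates to homogeneous no-interaction visitation and
    the detection fraction estimates the false-positive rate.
    """
    seeds = _child_seeds(seed, n_replicates)
    counts = {"attraction": 0, "avoidance": 0, "none": 0, "not_estimable": 0}
    for i in range(n_replicates):
        scen = couse_scenario(rho=rho, sigma=sigma, n_stations=n_stations,
                              season_days=season_days, seed=int(seeds[i]))
        config = AnalysisConfig(seed=int(seeds[i]))
        visits, stations = _simulate_visits(scen, config)
        res = couse_test(visits, "sp1", "sp2", stations, config)
        counts[res.classification] += 1
    return {
        "avoidance_rate": counts["avoidance"] / n_replicates,
        "attraction_rate": counts["attraction"] / n_replicates,
        "detection_rate": (counts["avoidance"] + counts["attraction"])
        / n_replicates,
        "counts": counts, "n_replicates": n_replicates,
    }
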