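"""Temporal attraction: does one species follow another to a plant?

The survey carries a facilitation kernel: for 2 hours after each sp1
visit, sp2's visit rate at that plant is multiplied by 10 (think of an
ungulate knocking ripe fruit within reach of a smaller frugivore). The
observed mean time difference (OMTD) from each sp1 visit to the first
later sp2 visit at the same plant is compared with expected-lag
intervals from two nulls: lags across plants >100 m apart (station-pair
null) and lags after reassigning every visit to a random different
plant (permutation null, 1000 iterations). OMTD below the 95% interval
means attraction; above it, aversion.
"""
from covisit import (AnalysisConfig, cluster_visits, excitation_scenario,
                     simulate, temporal_test)

scenario = excitation_scenario(effect=10.0, duration_hours=2.0, seed=11)
detections, stations, truth = simulate(scenario)
visits = cluster_visits(detections, window_minutes=5)
config = AnalysisConfig(seed=11)

for model, label in (("2", "station-pair null (>100 m)"),
                     ("3", "permutation null (1000 iterations)")):
    print(f"--- {label} ---")
    for pair in (("sp1", "sp2"), ("sp2", "sp1")):
        r = temporal_test(visits, pair[0], pair[1], stations, config, model)
        print(f"{pair[0]}->{pair[1]}: OMTD {r.omtd:5.2f} h "
              f"(n = {r.n_obs}), expected 95% interval "
              f"[{r.lower_95:.2f}, {r.upper_95:.2f}] -> {r.classification}")
    print()
print("The trigger->responder pair shows OMTD far below the expected")
print("interval (attraction); the reverse order, which the kernel does")
print("not affect, stays inside it.")
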