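"""Simulate a camera-trap survey and cluster photos into visits.

Two frugivore species visit 20 monitored fruiting plants for 60 days;
each visit triggers a three-photo burst. Photos are then clustered into
independent visits with the 5-minute rule: a photo starts a new visit
of its species at its station only if more than 5 minutes passed since
that species' previous photo there.
"""
from covisit import cluster_visits, no_interaction_scenario, simulate

scenario = no_interaction_scenario(n_species=2, n_stations=20,
                                   season_days=60, baseline_rate=0.5,
                                   seed=42)
detections, stations, truth = simulate(scenario)
visits5 = cluster_visits(detections, window_minutes=5)
visits30 = cluster_visits(detections, window_minutes=30)

print(f"photos:          {len(detections)}")
print(f"visits (5 min):  {len(visits5)}")
print(f"visits (30 min): {len(visits30)}")
print(f"per species:     {visits5.groupby('species').size().to_dict()}")
print()
print("Each species averages ~0.5 visits/station/day over 60 days and 20")
print("stations (~600 visits); the stricter 30-min window merges visits")
print("closer than 30 min, so it never yields more visits than the 5-min")
print("window.")
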