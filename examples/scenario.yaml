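# Example simulation scenario for `covisit simulate`.
# Two frugivores at 20 monitored plants for 60 days; the cow transiently
# facilitates fox visits (x8 rate for 2 h) at the plant it just visited,
# and both species visit larger crops more often. The fox is nocturnal.
species:
  - name: red_fox
    baseline_rate: 0.4          # visits / station / day
    functional_role: legitimate_disperser
    circadian:                  # (peak hour, concentration, weight)
      - [23.0, 2.0, 0.7]
      - [5.0, 2.0, 0.3]
    crop_affinity: 0.003        # log-linear, per fruit
  - name: cow
    baseline_rate: 0.8
    functional_role: seed_predator
kernels:
  - trigger: cow
    responder: red_fox
    effect: 8.0
    duration_hours: 2.0
n_stations: 20
side_m: 1000.0
season_days: 60.0
photo_burst: 3
interaction_prob: 0.6
seed: 42
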