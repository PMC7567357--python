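# Methods

This note documents the statistical model behind each analysis stage,
the defaults and why they hold, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would
otherwise have to reverse-engineer.

## Visit clustering

Detections are chained per (station, species): a photo opens a new
visit iff the gap to the immediately previous photo of that species at
that station *strictly exceeds* the independence window; a gap of
exactly the window continues the visit. Chaining to the previous record
(rather than to the visit's first record) is the standard
"independent event" convention in camera-trap work and makes the visit
count non-increasing in the window — the 30-min robustness window can
only merge, never split, 5-min visits. The visit's timestamp used by
every lag computation is its first photo: the triggering photo marks
the animal's arrival. Whether the first or last photo anchors a visit
is a genuinely open convention; first-photo is adopted and noted here
because switching to last-photo shifts lags by the (usually short)
visit duration.

Timestamps are compared at second resolution; identical timestamps of
different species are legal and yield a zero lag, which is skipped by
default (below).

## Spatial co-use contrast

Per ordered pair (sp1, sp2), valid stations split into PV / PNV by sp2
presence under the active scope. sp1's per-station visit counts are
regressed on the PV indicator with a Poisson log-link GLM
(statsmodels); without an effort offset the indicator's MLE equals
log(mean_PV / mean_PNV), so the GLM is exactly a two-group rate-ratio
test with a Wald p-value. Classification at alpha = 0.05: attraction if
significant and mean_PV > mean_PNV, avoidance if reversed,
`not_estimable` when a group is empty or all-zero (the log rate ratio
diverges). Per-station *counts* (not counts per active day) are the
response; an optional log(effort-days) offset is available when camera
activity differs across stations, and a Benjamini–Hochberg column is
available for all-pairs tables (classification stays on raw p-values,
matching the uncorrected convention of the analysis this mirrors).

Known limitation: a plain Poisson contrast assumes within-group
homogeneity of station rates. Under strong independent per-station
heterogeneity the counts are overdispersed and the Wald test is
anti-conservative — group-mean noise grows with the heterogeneity
sigma while the nominal Poisson standard error keeps shrinking with
total counts. Detected spatial associations for species with strong
station preferences of independent origin (territories, microhabitat)
should be read as "shared/segregated space use", not behavioural
response; the quasi-Poisson or mixed-model route is deliberately out
of scope.

## Temporal null models

The lag metric: for each sp1 visit at station s, the time to the first
strictly later sp2 visit at s, kept if ≤ 36 h. Each sp1 visit
contributes at most one lag; several sp1 visits may map to the same sp2
visit (repeated approaches before the partner arrives all carry
information). Simultaneous visits are excluded by default so that a tie
is not double-counted as lag 0 in both orders; `include_zero_lag=True`
restores them. The implementation is a vectorised station-major
searchsorted; tests pin it to an O(n²) brute-force scan.

**Station-pair null.** Expected lags use the same metric across every
ordered pair of valid stations strictly farther apart than the
independence distance (all eligible pairs, not a sample — the estimator
is deterministic given the data). Distance is planar Euclidean on the
supplied metric coordinates; geographic coordinates must be projected
first. The observed statistic is a *mean* (OMTD), so the comparison
interval is built from the bootstrap distribution of the mean of the
expected lags — 2000 resamples of size n_obs drawn with replacement.
Percentiles of raw lags (available via `model2_raw_percentiles`) would
compare a mean against a value distribution, which is anti-conservative
and inconsistent with the permutation null, whose iteration means
naturally form a distribution of means.

**Permutation null.** Each iteration reassigns every visit to a
uniformly drawn *different* valid station, keeping species, timestamp
and interaction flag; per-species counts and circadian rhythms are
preserved exactly by construction. Two visits may land on the same
station at the same time (nothing forbids co-location in the null).
The per-iteration mean lag over 1000 iterations forms the null
distribution; iterations with zero co-occurrences within the cap are
recorded as missing, excluded from the percentiles, and counted.
`respect_activity=True` restricts draws to stations whose camera was
active at the visit's time and is recommended when effort is uneven;
the default is off (the plain reassignment scheme), with a uniform
fallback and a logged warning for visits with no active alternative.

**Classification.** Attraction iff OMTD < lower 95% bound, aversion iff
above the upper bound, none inside; 90% bounds are reported for
display. Pairs with fewer than 4 observed lags or fewer than 4 expected
values (model 2: lags; model 3: non-missing iteration means) are
ineligible.

**Random streams.** All stochastic stages draw from a single run seed;
each species pair gets a child stream spawned with a key derived from
the pair name (CRC-32), so adding or removing pairs never perturbs the
others' results and all-pairs tables are order-independent.

## Synthetic generator

Each (station, species) stream is an inhomogeneous Poisson process with
intensity (per hour)

    lambda(t) = baseline * circadian(t) * exp(affinity * crop)
                * station_effect * kernel_mult(t)

- `baseline` in visits/station/day; `circadian` a von-Mises-mixture
  density integrating to 1 over 24 h (flat by default);
- `station_effect` a mean-one log-normal multiplier per station,
  optionally correlated between a species pair through a shared
  bivariate-normal log — the generative mechanism for spatial co-use
  structure;
- `kernel_mult` multiplies `effect` once per trigger-species visit at
  the *same* station within the past `duration_hours` (multiplicative
  across overlapping triggers), capped at 100 to keep the intensity
  bounded.

Sampling is exact thinning against a per-station upper bound (circadian
component maxima × a realised-overlap kernel bound); kernels must form
an acyclic trigger graph so triggers are simulated before responders —
a cycle raises a validation error rather than silently approximating a
mutually-exciting process. Each event expands to a three-photo burst
at 1-s spacing and carries a Bernoulli interaction flag. Identical
scenario + seed gives byte-identical output files.

What the generator does *not* emulate: animal movement between
stations (interaction is station-local by design), camera failure or
detection-probability < 1, seasonal ripening trends within a season,
and within-visit behaviour. Passing recovery tests therefore shows the
*inference machinery* is correct and calibrated under the stated
process, not that real surveys meet those assumptions.

## Study conditions used in validation

The replicated studies in `covisit.studies` (run by both the test
suite and `scripts/acceptance.py`) use 20 stations uniform in a 1-km
square, 60-day seasons and a 0.5 visits/station/day baseline — the
scale of a single-site, single-season plant-focused survey:

- **Type-I error** (permutation null): 200 homogeneous no-interaction
  replicates, 200 permutation iterations each. 200 iterations (rather
  than the analysis default of 1000) keeps a 200-replicate study at
  desk scale; interval percentiles at 200 iterations are slightly
  noisier, which if anything inflates the measured rate.
- **Power**: excitation kernel ×10 for 2 h — strong short-lived
  facilitation; detection is claimed for the trigger→responder order
  only, the reverse order doubling as an order-specificity check.
- **Spatial co-use recovery**: sigma = 1.0, rho = −0.9 — strong
  per-station preference heterogeneity with strong anticorrelation; sp2
  at 0.05 visits/station/day so it leaves some stations unvisited and
  both PV and PNV are populated. The false-positive arm uses the
  homogeneous no-interaction scenario (sigma = 0); as noted above, a
  plain Poisson contrast has no controlled error rate under strong
  *independent* heterogeneity, so the null condition of interest is
  "no shared spatial structure" in an otherwise homogeneous survey.

## Numerical choices and degenerate inputs

- Strict inequalities throughout: gap > window starts a visit;
  distance > threshold makes a station pair independent; lag > 0 for
  the strictly-later rule.
- Empty inputs flow through: empty detections give empty visit tables,
  empty lag sets give ineligible classifications, and the pipeline
  exits 0 with empty result files (validation failures exit 2).
- `not_estimable` co-use results still report group means and the
  ratio (`inf` when PNV is all-zero), since the direction is often
  still interpretable.
- Permutation with exactly two stations is a deterministic swap; with
  one station it is an error.
- Bootstrap and permutation intervals use empirical percentiles
  (numpy's default linear interpolation); with 1000 iterations the
  2.5/97.5 bounds are interpolated between order statistics 25/26 and
  975/976.
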