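"""Temporal null models for interspecific attraction and aversion.

The observed statistic for an ordered species pair (sp_first, sp_second)
is the OMTD: the mean, over sp_first visits, of the time elapsed until
the first strictly later sp_second visit at the *same* station, keeping
only lags below the 36-h cap. The OMTD is compared with an interval of
expected mean lags built from one of two nulls:

* station-pair null (model "2"): the same first-later lag computed
  across every ordered pair of stations farther apart than the spatial
  independence distance (100 or 200 m), where no direct behavioural
  interaction is possible; the interval is a bootstrap distribution of
  the mean of those expected lags.
* occurrence-permutation null (model "3"): each visit keeps its species,
  timestamp and interaction flag but is reassigned to a uniformly drawn
  *different* valid station; per-species visit counts and circadian
  rhythms are exactly preserved. The per-iteration mean lag over many
  iterations forms the null distribution of means.

OMTD below the lower 95% bound is classified as attraction, above the
upper bound as aversion, inside as none; pairs with fewer than
``min_obs`` observed or expected values are ineligible.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import PermutationImpossibleError, ValidationError
from .events import scope_visits

logger = logging.getLogger(__name__)

CLASS_ATTRACTION = "attraction"
CLASS_AVERSION = "aversion"
CLASS_NONE = "none"
CLASS_INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class LagSet:
    """Interspecific first-later lags (hours) for one ordered pair."""

    sp_first: str
    sp_second: str
    lags: np.ndarray
    source: str  # observed | spatial_null | permutation_iteration


@dataclass(frozen=True)
class TemporalNullResult:
    sp_first: str
    sp_second: str
    model: str  # "2" (station-pair) or "3" (permutation)
    omtd: float
    n_obs: int
    n_exp: int
    lower_95: float
    upper_95: float
    lower_90: float
    upper_90: float
    classification: str


def pair_rng(seed, sp_first: str, sp_second: str) -> np.random.Generator:
    """Stable per-pair random stream.

    Spawned from the run seed with a spawn key derived from the pair
    name, so adding or removing other pairs never perturbs this pair's
    draws.
    """
    key = zlib.crc32(f"{sp_first}\x00{sp_second}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _hours(times: pd.Series, ref) -> np.ndarray:
    return ((times - ref) / pd.Timedelta(hours=1)).to_numpy(float)


def _first_later_lags(t_first: np.ndarray, s_first: np.ndarray,
                      t_second: np.ndarray, s_second: np.ndarray,
                      max_lag: float, include_zero: bool,
                      span: float) -> np.ndarray:
    """Lag from each (t_first, station) to the first later t_second at
    the same station, vectorised with a station-major composite key.

    ``span`` must strictly exceed every time value so station blocks of
    the composite key cannot overlap.
    """
    if t_first.size == 0 or t_second.size == 0:
        return np.empty(0, dtype=float)
    key2 = s_second * span + t_second
    order = np.argsort(key2, kind="stable")
    key2 = key2[order]
    t2 = t_second[order]
    s2 = s_second[order]
    side = "left" if include_zero else "right"
    idx = np.searchsorted(key2, s_first * span + t_first, side=side)
    ok = idx < key2.size
    idx_c = np.minimum(idx, key2.size - 1)
    lag = t2[idx_c] - t_first
    ok &= s2[idx_c] == s_first
    ok &= lag <= max_lag
    return lag[ok]


class _PairData:
    """Pre-extracted arrays for one ordered species pair."""

    def __init__(self, visits: pd.DataFrame, sp_first: str, sp_second: str,
                 station_ids: pd.Index, scope: str):
        sub = scope_visits(visits, scope)
        sub = sub[sub["station_id"].isin(station_ids)]
        self.station_ids = station_ids
        code = pd.Categorical(sub["station_id"], categories=station_ids).codes
        ref = sub["start_time"].min() if len(sub) else pd.Timestamp(0)
        t = _hours(sub["start_time"], ref)
        first = (sub["species"] == sp_first).to_numpy()
        second = (sub["species"] == sp_second).to_numpy()
        self.t1, self.s1 = t[first], code[first].astype(np.int64)
        self.t2, self.s2 = t[second], code[second].astype(np.int64)
        self.span = (float(t.max()) if len(sub) else 0.0) + 1.0


def observed_lags(visits: pd.DataFrame, sp_first: str, sp_second: str,
                  config: AnalysisConfig) -> LagSet:
    """Observed same-station first-later lags for (sp_first, sp_second).

    Each sp_first visit contributes at most one lag — to the earliest
    sp_second visit at the same station starting strictly later (ties
    are skipped unless ``include_zero_lag``) — and only if that lag is
    within ``max_lag_hours``. Several sp_first visits may map to the
    same sp_second visit. Lags are pooled over all stations in scope.
    """
    if sp_first == sp_second:
        raise ValidationError("species pair must be two distinct species")
    ids = pd.Index(visits["station_id"].unique())
    pd_ = _PairData(visits, sp_first, sp_second, ids, config.scope)
    lags = _first_later_lags(pd_.t1, pd_.s1, pd_.t2, pd_.s2,
                             config.max_lag_hours, config.include_zero_lag,
                             pd_.span)
    return LagSet(sp_first, sp_second, lags, "observed")


def station_distances(stations: pd.DataFrame) -> pd.DataFrame:
    """Planar Euclidean distance matrix over valid stations (meters).

    Coordinates must already be in a metric projection; longitude and
    latitude must be projected beforehand.
    """
    st = stations.loc[stations["valid"]]
    xy = st[["x_m", "y_m"]].to_numpy(float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    ids = st["station_id"].to_numpy()
    return pd.DataFrame(d, index=ids, columns=ids)


def spatial_null_lags(visits: pd.DataFrame, sp_first: str, sp_second: str,
                      stations: pd.DataFrame, config: AnalysisConfig,
                      min_distance_m: float | None = None) -> LagSet:
    """Expected lags from spatially independent station pairs.

    For every ordered pair of valid stations (A, B) strictly farther
    apart than the independence distance, each sp_first visit at A
    contributes the lag to the first strictly later sp_second visit at
    B within the cap; lags are pooled over all eligible pairs. An empty
    result (no station pair beyond the threshold, or no later visits)
    renders the pair ineligible downstream.
    """
    if min_distance_m is None:
        min_distance_m = config.min_distance_m
    dist = station_distances(stations)
    ids = dist.index
    pd_ = _PairData(visits, sp_first, sp_second, pd.Index(ids), config.scope)
    d = dist.to_numpy()
    all_lags = []
    for b in range(len(ids)):
        if not (pd_.s2 == b).any():
            continue
        eligible = np.flatnonzero(d[:, b] > min_distance_m)  # excludes A == B
        if eligible.size == 0:
            continue
        mask1 = np.isin(pd_.s1, eligible)
        if not mask1.any():
            continue
        t1 = pd_.t1[mask1]
        t2b = np.sort(pd_.t2[pd_.s2 == b])
        side = "left" if config.include_zero_lag else "right"
        idx = np.searchsorted(t2b, t1, side=side)
        ok = idx < t2b.size
        lag = t2b[np.minimum(idx, t2b.size - 1)] - t1
        ok &= lag <= config.max_lag_hours
        all_lags.append(lag[ok])
    lags = (np.concatenate(all_lags) if all_lags else np.empty(0, dtype=float))
    return LagSet(sp_first, sp_second, lags, "spatial_null")


def _interval(values: np.ndarray, levels) -> tuple[float, float, float, float]:
    hi, lo = levels  # e.g. (0.95, 0.90)
    l95, u95 = np.percentile(values, [100 * (1 - hi) / 2, 100 * (1 + hi) / 2])
    l90, u90 = np.percentile(values, [100 * (1 - lo) / 2, 100 * (1 + lo) / 2])
    return float(l95), float(u95), float(l90), float(u90)


def _classify(omtd: float, bounds, n_obs: int, n_exp: int, min_obs: int) -> str:
    if n_obs < min_obs or n_exp < min_obs:
        return CLASS_INELIGIBLE
    l95, u95 = bounds
    if omtd < l95:
        return CLASS_ATTRACTION
    if omtd > u95:
        return CLASS_AVERSION
    return CLASS_NONE


def classify_model2(observed: LagSet, expected: LagSet, config: AnalysisConfig,
                    rng: np.random.Generator | None = None) -> TemporalNullResult:
    """Classify a pair against the station-pair (spatial) null.

    The interval is built from the bootstrap distribution of the mean
    of the expected lags (``bootstrap_resamples`` resamples of size
    ``n_obs``, drawn with replacement), a like-for-like comparison for
    a mean statistic; percentiles of the raw expected lags are available
    via ``model2_raw_percentiles``.
    """
    if rng is None:
        rng = pair_rng(config.seed, observed.sp_first, observed.sp_second)
    n_obs = observed.lags.size
    n_exp = expected.lags.size
    omtd = float(observed.lags.mean()) if n_obs else float("nan")
    if n_obs < config.min_obs or n_exp < config.min_obs:
        nan = float("nan")
        return TemporalNullResult(observed.sp_first, observed.sp_second, "2",
                                  omtd, n_obs, n_exp, nan, nan, nan, nan,
                                  CLASS_INELIGIBLE)
    if config.model2_raw_percentiles:
        dist = expected.lags
    else:
        dist = rng.choice(expected.lags,
                          size=(config.bootstrap_resamples, n_obs),
                          replace=True).mean(axis=1)
    l95, u95, l90, u90 = _interval(dist, config.interval_levels)
    cls = _classify(omtd, (l95, u95), n_obs, n_exp, config.min_obs)
    return TemporalNullResult(observed.sp_first, observed.sp_second, "2",
                              omtd, n_obs, n_exp, l95, u95, l90, u90, cls)


def permute_occurrences(visits: pd.DataFrame, stations: pd.DataFrame,
                        rng: np.random.Generator,
                        respect_activity: bool = False) -> pd.DataFrame:
    """Reassign every visit to a uniformly drawn *different* station.

    Species, timestamps and interaction flags are untouched, so
    per-species visit counts and observed circadian rhythms are exactly
    preserved; only the spatial assignment is randomised. With
    ``respect_activity`` the draw is restricted to stations whose camera
    was active at the visit's start time; a visit with no active
    alternative falls back to a uniform draw over all other stations
    with a logged warning.
    """
    st = stations.loc[stations["valid"]].reset_index(drop=True)
    ids = st["station_id"].to_numpy()
    k = len(ids)
    if k < 2:
        raise PermutationImpossibleError(
            "occurrence permutation needs at least 2 valid stations")
    unknown = set(visits["station_id"]) - set(ids)
    if unknown:
        raise ValidationError(f"visits at non-valid stations: {sorted(unknown)}")
    orig = pd.Categorical(visits["station_id"], categories=ids).codes.astype(np.int64)
    draw = rng.integers(0, k - 1, size=len(visits))
    new = draw + (draw >= orig)
    if respect_activity:
        start = st["active_start"].to_numpy()
        end = st["active_end"].to_numpy()
        ts = visits["start_time"].to_numpy()
        active = (ts[:, None] >= start[None, :]) & (ts[:, None] <= end[None, :])
        active[np.arange(len(visits)), orig] = False
        n_active = active.sum(axis=1)
        fallback = n_active == 0
        if fallback.any():
            logger.warning("%d visits had no active alternative station; "
                           "falling back to a uniform draw", int(fallback.sum()))
        redo = (~active[np.arange(len(visits)), new]) & ~fallback
        for i in np.flatnonzero(redo):
            new[i] = rng.choice(np.flatnonzero(active[i]))
    out = visits.copy()
    out["station_id"] = ids[new]
    return out


def null3_distribution(visits: pd.DataFrame, sp_first: str, sp_second: str,
                       stations: pd.DataFrame, config: AnalysisConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-iteration mean lags under the occurrence-permutation null.

    Returns an array of length ``config.iterations``; iterations whose
    permutation yields no co-occurrence within the lag cap are NaN and
    are excluded from the percentile bounds downstream. Deterministic
    under a fixed config seed (per-pair stream).
    """
    if rng is None:
        rng = pair_rng(config.seed, sp_first, sp_second)
    st = stations.loc[stations["valid"]].reset_index(drop=True)
    ids = pd.Index(st["station_id"])
    k = len(ids)
    if k < 2:
        raise PermutationImpossibleError(
            "occurrence permutation needs at least 2 valid stations")
    pd_ = _PairData(visits, sp_first, sp_second, ids, config.scope)
    n1, n2 = pd_.t1.size, pd_.t2.size
    means = np.full(config.iterations, np.nan)
    if n1 == 0 or n2 == 0:
        return means
    orig = np.concatenate([pd_.s1, pd_.s2])
    if (orig < 0).any():
        raise ValidationError("visits at stations missing from the station table")
    for it in range(config.iterations):
        draw = rng.integers(0, k - 1, size=orig.size)
        new = draw + (draw >= orig)
        lags = _first_later_lags(pd_.t1, new[:n1], pd_.t2, new[n1:],
                                 config.max_lag_hours, config.include_zero_lag,
                                 pd_.span)
        if lags.size:
            means[it] = lags.mean()
    return means


def classify_model3(omtd: float, n_obs: int, iteration_means: np.ndarray,
                    config: AnalysisConfig, sp_first: str = "",
                    sp_second: str = "") -> TemporalNullResult:
    """Classify a pair against the permutation null distribution of means."""
    finite = np.asarray(iteration_means, float)
    finite = finite[np.isfinite(finite)]
    n_exp = finite.size
    if n_obs < config.min_obs or n_exp < config.min_obs:
        nan = float("nan")
        return TemporalNullResult(sp_first, sp_second, "3", omtd, n_obs, n_exp,
                                  nan, nan, nan, nan, CLASS_INELIGIBLE)
    l95, u95, l90, u90 = _interval(finite, config.interval_levels)
    cls = _classify(omtd, (l95, u95), n_obs, n_exp, config.min_obs)
    return TemporalNullResult(sp_first, sp_second, "3", omtd, n_obs, n_exp,
                              l95, u95, l90, u90, cls)


def temporal_test(visits: pd.DataFrame, sp_first: str, sp_second: str,
                  stations: pd.DataFrame, config: AnalysisConfig,
                  model: str) -> TemporalNullResult:
    """Run one temporal null ("2" station-pair, "3" permutation) end to end."""
    obs = observed_lags(visits, sp_first, sp_second, config)
    rng = pair_rng(config.seed, sp_first, sp_second)
    if str(model) == "2":
        exp = spatial_null_lags(visits, sp_first, sp_second, stations, config)
        return classify_model2(obs, exp, config, rng=rng)
    if str(model) == "3":
        means = null3_distribution(visits, sp_first, sp_second, stations,
                                   config, rng=rng)
        omtd = float(obs.lags.mean()) if obs.lags.size else float("nan")
        return classify_model3(omtd, obs.lags.size, means, config,
                               sp_first, sp_second)
    raise ValidationError(f"unknown temporal null model {model!r}")


def all_pairs_temporal(visits: pd.DataFrame, stations: pd.DataFrame,
                       config: AnalysisConfig, model: str,
                       species=None) -> pd.DataFrame:
    """Temporal null results for every ordered species pair."""
    sub = scope_visits(visits, config.scope)
    if species is None:
        species = sorted(sub["species"].unique())
    rows = []
    for sp1 in species:
        for sp2 in species:
            if sp1 == sp2:
                continue
            r = temporal_test(visits, sp1, sp2, stations, config, model)
            rows.append({
                "sp_first": r.sp_first, "sp_second": r.sp_second,
                "model": r.model, "scope": config.scope,
                "window_minutes": config.window_minutes,
                "min_distance_m": config.min_distance_m,
                "OMTD": r.omtd, "n_obs": r.n_obs, "n_exp": r.n_exp,
                "lower_95": r.lower_95, "upper_95": r.upper_95,
                "lower_90": r.lower_90, "upper_90": r.upper_90,
                "classification": r.classification, "seed": config.seed,
            })
    return pd.DataFrame(rows)
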