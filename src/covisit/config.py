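"""Analysis configuration.

All tunable constants of the analytical pipeline live here: the visit
independence window (5 or 30 minutes), the maximum interspecific lag
considered biologically meaningful (36 h), the spatial independence
distance for the station-pair temporal null (100 or 200 m), the minimum
number of observed and expected lags for a species pair to be eligible
(4), the number of permutation iterations (1000) and the interval levels
used for classification (95% with 90% also reported).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import yaml

from .errors import ValidationError

SCOPE_ALL = "all_visits"
SCOPE_INTERACTIONS = "interactions_only"
VALID_SCOPES = (SCOPE_ALL, SCOPE_INTERACTIONS)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters shared by every analysis stage.

    Parameters
    ----------
    window_minutes : float
        Independence window used to cluster photos into visits. A photo
        starts a new visit of its species at its station iff its gap to
        the previous photo strictly exceeds this window. Conventional
        values are 5 (liberal) and 30 (strict).
    max_lag_hours : float
        Interspecific lags longer than this are discarded: no behavioural
        interaction is assumed over a longer horizon.
    min_distance_m : float
        Minimum planar distance between two stations for their visit
        streams to be treated as spatially independent (temporal null
        model built from station pairs). 100 or 200 m are typical.
    min_obs : int
        Minimum number of observed lags *and* of expected lags for an
        ordered species pair to be classified; below it the result is
        ``ineligible``.
    iterations : int
        Number of occurrence-permutation iterations for the permutation
        temporal null.
    interval_levels : tuple of float
        Two-sided interval levels, largest first. The first (95%) drives
        classification; the second (90%) is reported alongside.
    scope : str
        ``all_visits`` analyses every visit; ``interactions_only``
        restricts to visits whose interaction flag is 1 (animal touching
        the plant).
    alpha : float
        Significance level of the spatial co-use Poisson contrast.
    bootstrap_resamples : int
        Resamples used to build the bootstrap distribution of the mean
        expected lag (station-pair null).
    model2_raw_percentiles : bool
        If True, interval bounds of the station-pair null are percentiles
        of the raw expected lags instead of bootstrap means.
    include_zero_lag : bool
        If True, simultaneous visits contribute a zero lag; by default
        they are skipped and the next strictly later visit is used.
    respect_activity : bool
        If True, occurrence permutation only reassigns a visit to
        stations whose camera was active at the visit's timestamp.
    effort_offset : bool
        If True, the co-use Poisson contrast includes log(effort days)
        as an offset.
    seed : int or None
        Seed of the single random source all stochastic stages draw from.
    """

    window_minutes: float = 5.0
    max_lag_hours: float = 36.0
    min_distance_m: float = 100.0
    min_obs: int = 4
    iterations: int = 1000
    interval_levels: tuple[float, float] = (0.95, 0.90)
    scope: str = SCOPE_ALL
    alpha: float = 0.05
    bootstrap_resamples: int = 2000
    model2_raw_percentiles: bool = False
    include_zero_lag: bool = False
    respect_activity: bool = False
    effort_offset: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_minutes <= 0:
            raise ValidationError("window_minutes must be > 0")
        if self.max_lag_hours <= 0:
            raise ValidationError("max_lag_hours must be > 0")
        if self.min_obs < 1:
            raise ValidationError("min_obs must be >= 1")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.scope not in VALID_SCOPES:
            raise ValidationError(
                f"scope must be one of {VALID_SCOPES}, got {self.scope!r}"
            )
        levels = tuple(self.interval_levels)
        if len(levels) != 2 or not all(0 < l < 1 for l in levels):
            raise ValidationError("interval_levels must be two values in (0, 1)")
        if levels[0] < levels[1]:
            raise ValidationError("interval_levels must be largest first")
        object.__setattr__(self, "interval_levels", levels)
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "interval_levels" in kwargs:
            kwargs["interval_levels"] = tuple(kwargs["interval_levels"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interval_levels"] = list(self.interval_levels)
        return d
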