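"""Synthetic camera-trap detection streams with known ground truth.

Each species visits each station according to an inhomogeneous Poisson
process with intensity (visits per hour)

    lambda(t) = baseline_rate * circadian(t mod 24) * crop_mult
                * station_effect * kernel_mult(t)

where ``circadian`` is a von-Mises-mixture density integrating to 1
over 24 h, ``crop_mult`` is a log-linear response to the station's fruit
crop, ``station_effect`` is a mean-one log-normal per-station random
multiplier (optionally correlated or anticorrelated between a species
pair, the generative mechanism for spatial co-use signal), and
``kernel_mult`` multiplies one factor ``effect`` for every visit of a
trigger species at the *same* station within the past ``duration_hours``
(effect > 1: excitation/facilitation; < 1: inhibition/avoidance),
capped at a configurable maximum. Events are drawn exactly by thinning
against a per-station intensity upper bound and expanded into short
photo bursts, emulating a camera taking a three-photo sequence.

Kernels must form an acyclic trigger graph: trigger species are
simulated before their responders so the conditional intensity of each
responder is fully known.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import i0

from .errors import ValidationError

SEASON_START = pd.Timestamp("2018-10-01 00:00:00")

ROLE_LEGITIMATE = "legitimate_disperser"
ROLE_PREDATOR = "seed_predator"
ROLE_PULP = "pulp_feeder"
ROLE_MIXED = "mixed"
ROLES = (ROLE_LEGITIMATE, ROLE_PREDATOR, ROLE_PULP, ROLE_MIXED)


@dataclass(frozen=True)
class SpeciesProfile:
    """Visitation profile of one species.

    ``circadian`` is a list of (peak_hour, concentration, weight) bumps;
    empty means a flat (uniform) 24-h rhythm. ``crop_affinity`` is the
    log-linear slope per fruit: multiplier = exp(affinity * crop_size),
    so realistic values are small (e.g. 0.005 per fruit).
    """

    name: str
    baseline_rate: float  # visits / station / day
    functional_role: str = ROLE_MIXED
    circadian: tuple = ()
    crop_affinity: float = 0.0

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValidationError(f"{self.name}: baseline_rate must be >= 0")
        if self.functional_role not in ROLES:
            raise ValidationError(
                f"{self.name}: functional_role must be one of {ROLES}")
        for bump in self.circadian:
            peak, kappa, w = bump
            if not (0 <= peak < 24) or kappa < 0 or w <= 0:
                raise ValidationError(f"{self.name}: bad circadian bump {bump}")


@dataclass(frozen=True)
class InteractionKernel:
    """Short-lived same-station cross-species rate modulation."""

    trigger: str
    responder: str
    effect: float  # rate multiplier; >1 excitation, <1 inhibition
    duration_hours: float
    spatial_scope: str = "same_station"

    def __post_init__(self):
        if self.effect <= 0:
            raise ValidationError("kernel effect must be > 0")
        if self.duration_hours <= 0:
            raise ValidationError("kernel duration_hours must be > 0")
        if self.spatial_scope != "same_station":
            raise ValidationError("only same_station kernels are supported")
        if self.trigger == self.responder:
            raise ValidationError("kernel trigger and responder must differ")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative scenario: stations, season, species, couplings."""

    species: tuple
    kernels: tuple = ()
    n_stations: int = 20
    side_m: float = 1000.0
    crop_meanlog: float = 4.5  # log fruit count; exp(4.5) ~ 90 fruits
    crop_sdlog: float = 0.8
    season_days: float = 60.0
    station_effect_sigma: float = 0.0
    effect_correlation: tuple | None = None  # (species_a, species_b, rho)
    photo_burst: int = 3
    burst_spacing_s: float = 1.0
    interaction_prob: float = 0.5
    intensity_cap: float = 100.0
    site: str = "SITE1"
    seed: int = 0

    def __post_init__(self):
        if self.n_stations < 1 or self.season_days <= 0 or self.photo_burst < 1:
            raise ValidationError("counts and season length must be positive")
        if self.station_effect_sigma < 0:
            raise ValidationError("station_effect_sigma must be >= 0")
        if self.intensity_cap < 1:
            raise ValidationError("intensity_cap must be >= 1")
        if not 0 <= self.interaction_prob <= 1:
            raise ValidationError("interaction_prob must be in [0, 1]")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names")
        for k in self.kernels:
            if k.trigger not in names or k.responder not in names:
                raise ValidationError(
                    f"kernel references unknown species {k.trigger}->{k.responder}")
        if self.effect_correlation is not None:
            a, b, rho = self.effect_correlation
            if a not in names or b not in names or a == b:
                raise ValidationError("effect_correlation must name two species")
            if not -1 <= rho <= 1:
                raise ValidationError("correlation must be in [-1, 1]")
        _topo_order(names, self.kernels)  # raises on a cyclic trigger graph

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def _topo_order(names, kernels) -> list[str]:
    deps = {n: set() for n in names}
    for k in kernels:
        deps[k.responder].add(k.trigger)
    order, done = [], set()
    while len(order) < len(names):
        ready = [n for n in names if n not in done and deps[n] <= done]
        if not ready:
            raise ValidationError("kernel trigger graph is cyclic")
        for n in ready:
            order.append(n)
            done.add(n)
    return order


def circadian_density(profile: SpeciesProfile, hours: np.ndarray) -> np.ndarray:
    """24-h activity density (1/h), integrating to 1 over a day."""
    h = np.asarray(hours, float) % 24.0
    if not profile.circadian:
        return np.full_like(h, 1.0 / 24.0)
    bumps = np.array(profile.circadian, float)
    w = bumps[:, 2] / bumps[:, 2].sum()
    ang = 2 * np.pi * (h[..., None] - bumps[:, 0]) / 24.0
    dens = np.exp(bumps[:, 1] * np.cos(ang)) / (24.0 * i0(bumps[:, 1]))
    return (w * dens).sum(-1)


def _circadian_max(profile: SpeciesProfile) -> float:
    # sum of component maxima: a safe upper bound for thinning
    if not profile.circadian:
        return 1.0 / 24.0
    bumps = np.array(profile.circadian, float)
    w = bumps[:, 2] / bumps[:, 2].sum()
    return float((w * np.exp(bumps[:, 1]) / (24.0 * i0(bumps[:, 1]))).sum())


def _station_effects(scenario: ScenarioConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Mean-one log-normal per-station rate multipliers per species."""
    k = scenario.n_stations
    sigma = scenario.station_effect_sigma
    names = [sp.name for sp in scenario.species]
    if sigma == 0:
        return {n: np.ones(k) for n in names}
    z = {n: rng.standard_normal(k) for n in names}
    if scenario.effect_correlation is not None:
        a, b, rho = scenario.effect_correlation
        z[b] = rho * z[a] + np.sqrt(1 - rho ** 2) * z[b]
    return {n: np.exp(sigma * z[n] - sigma ** 2 / 2) for n in names}


def _kernel_bound(kernels, trigger_times: dict[str, np.ndarray],
                  cap: float) -> float:
    """Upper bound on the kernel multiplier given realised trigger times."""
    bound = 1.0
    for k in kernels:
        if k.effect <= 1.0:
            continue
        trig = trigger_times[k.trigger]
        if trig.size == 0:
            continue
        idx = np.searchsorted(trig, trig - k.duration_hours, side="left")
        max_overlap = int((np.arange(trig.size) - idx).max()) + 1
        bound *= k.effect ** max_overlap
        if bound >= cap:
            return cap
    return min(bound, cap)


def _kernel_multiplier(t: np.ndarray, kernels,
                       trigger_times: dict[str, np.ndarray],
                       cap: float) -> np.ndarray:
    mult = np.ones_like(t)
    for k in kernels:
        trig = trigger_times[k.trigger]
        if trig.size == 0:
            continue
        n_active = (np.searchsorted(trig, t, side="left")
                    - np.searchsorted(trig, t - k.duration_hours, side="left"))
        mult *= k.effect ** n_active
    return np.minimum(mult, cap)


def simulate(scenario: ScenarioConfig):
    """Draw one synthetic survey.

    Returns ``(detections, stations, truth)`` DataFrames in the same
    layout the readers in :mod:`covisit.events` expect. Byte-identical
    output under identical scenario + seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    k = scenario.n_stations
    station_ids = [f"P{i + 1:03d}" for i in range(k)]
    xy = rng.uniform(0, scenario.side_m, size=(k, 2))
    crops = np.round(rng.lognormal(scenario.crop_meanlog, scenario.crop_sdlog, k))
    effects = _station_effects(scenario, rng)
    t_end = scenario.season_days * 24.0

    profiles = {sp.name: sp for sp in scenario.species}
    order = _topo_order(list(profiles), scenario.kernels)
    kernels_for = {n: [kk for kk in scenario.kernels if kk.responder == n]
                   for n in profiles}
    events: dict[tuple[str, int], np.ndarray] = {}
    for name in order:
        sp = profiles[name]
        d_max = _circadian_max(sp)
        for s in range(k):
            rate_scale = (sp.baseline_rate
                          * np.exp(sp.crop_affinity * crops[s])
                          * effects[name][s])
            trig = {kk.trigger: events[(kk.trigger, s)]
                    for kk in kernels_for[name]}
            kb = _kernel_bound(kernels_for[name], trig, scenario.intensity_cap)
            m = rate_scale * d_max * kb  # events per hour, upper bound
            n_cand = rng.poisson(m * t_end) if m > 0 else 0
            if n_cand == 0:
                events[(name, s)] = np.empty(0)
                continue
            t = np.sort(rng.uniform(0, t_end, n_cand))
            lam = (rate_scale * circadian_density(sp, t)
                   * _kernel_multiplier(t, kernels_for[name], trig,
                                        scenario.intensity_cap))
            accept = rng.uniform(0, m, n_cand) < lam
            events[(name, s)] = t[accept]

    rows = []
    for name in order:
        for s in range(k):
            t = events[(name, s)]
            if t.size == 0:
                continue
            flags = (rng.uniform(size=t.size) < scenario.interaction_prob)
            for ti, fi in zip(t, flags):
                rows.append((station_ids[s], name, ti, int(fi)))
    burst_offsets = (np.arange(scenario.photo_burst)
                     * scenario.burst_spacing_s / 3600.0)
    if rows:
        ev = pd.DataFrame(rows, columns=["station_id", "species", "t", "interaction"])
        rep = ev.loc[ev.index.repeat(scenario.photo_burst)].reset_index(drop=True)
        rep["t"] = rep["t"].to_numpy() + np.tile(burst_offsets, len(ev))
        ts = SEASON_START + pd.to_timedelta(
            np.round(rep["t"].to_numpy() * 3600.0), unit="s")
        detections = pd.DataFrame({
            "site": scenario.site,
            "station_id": rep["station_id"],
            "species": rep["species"],
            "timestamp": ts,
            "interaction": rep["interaction"],
        }).sort_values(["station_id", "species", "timestamp"],
                       kind="mergesort").reset_index(drop=True)
    else:
        detections = pd.DataFrame(
            columns=["site", "station_id", "species", "timestamp", "interaction"])

    stations = pd.DataFrame({
        "site": scenario.site,
        "station_id": station_ids,
        "x_m": xy[:, 0],
        "y_m": xy[:, 1],
        "crop_size": crops,
        "active_start": SEASON_START,
        "active_end": SEASON_START + pd.Timedelta(hours=t_end),
        "valid": True,
    })
    return detections, stations, ground_truth(scenario)


def ground_truth(scenario: ScenarioConfig) -> pd.DataFrame:
    """Expected classification per ordered species pair and null model.

    An excitation kernel trigger->responder makes the temporal truth of
    (trigger, responder) attraction (aversion for inhibition); a
    negative (positive) station-effect correlation makes the spatial
    co-use truth of the coupled pair avoidance (attraction); everything
    else is none.
    """
    names = [sp.name for sp in scenario.species]
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            temporal = "none"
            for kk in scenario.kernels:
                if kk.trigger == a and kk.responder == b and kk.effect != 1.0:
                    temporal = "attraction" if kk.effect > 1 else "aversion"
            couse = "none"
            if (scenario.effect_correlation is not None
                    and scenario.station_effect_sigma > 0):
                ca, cb, rho = scenario.effect_correlation
                if {a, b} == {ca, cb} and rho != 0:
                    couse = "attraction" if rho > 0 else "avoidance"
            rows.append({"sp_first": a, "sp_second": b,
                         "truth_temporal": temporal, "truth_couse": couse})
    return pd.DataFrame(rows)


# --- canned scenario builders -------------------------------------------------

def no_interaction_scenario(n_species: int = 2, n_stations: int = 20,
                            season_days: float = 60.0,
                            baseline_rate: float = 0.5,
                            seed: int = 0) -> ScenarioConfig:
    """Homogeneous independent visitation: the all-none ground truth."""
    species = tuple(SpeciesProfile(name=f"sp{i + 1}", baseline_rate=baseline_rate)
                    for i in range(n_species))
    return ScenarioConfig(species=species, n_stations=n_stations,
                          season_days=season_days, seed=seed)


def excitation_scenario(effect: float = 10.0, duration_hours: float = 2.0,
                        n_stations: int = 20, season_days: float = 60.0,
                        baseline_rate: float = 0.5,
                        seed: int = 0) -> ScenarioConfig:
    """Trigger sp1 transiently boosts responder sp2 at the same station.

    The defaults (x10 rate for 2 h) emulate strong short-lived
    facilitation, e.g. an ungulate making fruit accessible to a smaller
    frugivore; effect < 1 gives the predator-avoidance analogue.
    """
    species = (SpeciesProfile("sp1", baseline_rate, ROLE_PREDATOR),
               SpeciesProfile("sp2", baseline_rate, ROLE_LEGITIMATE))
    kernel = InteractionKernel("sp1", "sp2", effect, duration_hours)
    return ScenarioConfig(species=species, kernels=(kernel,),
                          n_stations=n_stations, season_days=season_days,
                          seed=seed)


def couse_scenario(rho: float = -0.9, sigma: float = 1.0,
                   sp1_rate: float = 0.5, sp2_rate: float = 0.05,
                   n_stations: int = 20, season_days: float = 60.0,
                   seed: int = 0) -> ScenarioConfig:
    """Spatial co-use structure via (anti)correlated station effects.

    sp2 is sparse (0.05 visits/station/day) so that it leaves a subset
    of stations unvisited, giving the PV/PNV partition both groups;
    sigma = 1 gives strong per-station preference heterogeneity and
    rho = -0.9 strong spatial avoidance (rho > 0 attraction, rho = 0 no
    coupling).
    """
    species = (SpeciesProfile("sp1", sp1_rate),
               SpeciesProfile("sp2", sp2_rate))
    return ScenarioConfig(species=species, n_stations=n_stations,
                          season_days=season_days,
                          station_effect_sigma=sigma,
                          effect_correlation=("sp1", "sp2", rho),
                          seed=seed)


# --- scenario file I/O --------------------------------------------------------

def load_scenario(path) -> ScenarioConfig:
    """Load a scenario from YAML mirroring :class:`ScenarioConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"scenario file {path} must contain a mapping")
    try:
        species = tuple(
            SpeciesProfile(
                name=sp["name"],
                baseline_rate=sp["baseline_rate"],
                functional_role=sp.get("functional_role", ROLE_MIXED),
                circadian=tuple(tuple(b) for b in sp.get("circadian", [])),
                crop_affinity=sp.get("crop_affinity", 0.0),
            ) for sp in data.pop("species"))
        kernels = tuple(
            InteractionKernel(
                trigger=kk["trigger"], responder=kk["responder"],
                effect=kk["effect"], duration_hours=kk["duration_hours"],
            ) for kk in data.pop("kernels", []))
        ec = data.pop("effect_correlation", None)
        if ec is not None:
            ec = (ec[0], ec[1], float(ec[2]))
        return ScenarioConfig(species=species, kernels=kernels,
                              effect_correlation=ec, **data)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"bad scenario file {path}: {exc}") from exc
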