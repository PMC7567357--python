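"""Spatial co-use contrast (null model 1) and crop-size correlations.

For an ordered species pair (sp1, sp2), valid stations are partitioned
into PV (visited by sp2 at least once under the active scope) and PNV
(camera data but no sp2 visit). Under the null hypothesis of no
interaction, sp1's mean visit count per station should not differ
between the two groups; a Poisson GLM with log link of sp1's per-station
counts on PV membership tests this. A significantly higher mean in PV
is read as spatial attraction, a significantly lower one as avoidance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import NotEstimableError, UndefinedCorrelationError, ValidationError
from .events import effort_days, scope_visits

CLASS_ATTRACTION = "attraction"
CLASS_AVOIDANCE = "avoidance"
CLASS_NONE = "none"
CLASS_NOT_ESTIMABLE = "not_estimable"


@dataclass(frozen=True)
class CoUsePartition:
    """Stations visited (PV) / not visited (PNV) by the second species."""

    sp2: str
    pv: frozenset
    pnv: frozenset


@dataclass(frozen=True)
class CoUseResult:
    sp1: str
    sp2: str
    n_pv: int
    n_pnv: int
    mean_pv: float
    mean_pnv: float
    ratio: float  # nan when undefined, inf when mean_pnv == 0 < mean_pv
    coefficient: float
    std_error: float
    p_value: float
    classification: str


def _valid_station_ids(stations: pd.DataFrame) -> pd.Index:
    return pd.Index(stations.loc[stations["valid"], "station_id"])


def partition_stations(visits: pd.DataFrame, sp2: str, stations: pd.DataFrame,
                       scope: str = "all_visits") -> CoUsePartition:
    """Partition valid stations into PV / PNV with respect to ``sp2``."""
    ids = _valid_station_ids(stations)
    if len(ids) == 0:
        raise ValidationError("no valid stations")
    sub = scope_visits(visits, scope)
    visited = set(sub.loc[sub["species"] == sp2, "station_id"]) & set(ids)
    return CoUsePartition(sp2=sp2, pv=frozenset(visited),
                          pnv=frozenset(set(ids) - visited))


def station_counts(visits: pd.DataFrame, species: str, stations: pd.DataFrame,
                   scope: str = "all_visits") -> pd.Series:
    """Per-valid-station visit counts for one species (zeros included)."""
    ids = _valid_station_ids(stations)
    sub = scope_visits(visits, scope)
    counts = (sub.loc[sub["species"] == species]
                 .groupby("station_id").size()
                 .reindex(ids, fill_value=0))
    counts.name = species
    return counts


def poisson_contrast(counts_pv, counts_pnv, offsets_pv=None, offsets_pnv=None):
    """Poisson log-link regression of counts on PV membership.

    Returns ``(coefficient, std_error, p_value)`` where the coefficient
    is the log rate ratio PV/PNV; without offsets its MLE equals
    log(mean_PV / mean_PNV). Raises :class:`NotEstimableError` when a
    group is empty or all-zero (the coefficient diverges).
    """
    y_pv = np.asarray(counts_pv, dtype=float)
    y_pnv = np.asarray(counts_pnv, dtype=float)
    if y_pv.size == 0 or y_pnv.size == 0:
        raise NotEstimableError("empty PV or PNV group")
    if (y_pv < 0).any() or (y_pnv < 0).any():
        raise ValidationError("counts must be non-negative")
    if y_pv.sum() == 0 or y_pnv.sum() == 0:
        raise NotEstimableError("all counts zero in one group")
    y = np.concatenate([y_pv, y_pnv])
    indicator = np.concatenate([np.ones_like(y_pv), np.zeros_like(y_pnv)])
    X = sm.add_constant(indicator)
    offset = None
    if offsets_pv is not None or offsets_pnv is not None:
        offset = np.concatenate([np.asarray(offsets_pv, float),
                                 np.asarray(offsets_pnv, float)])
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def couse_test(visits: pd.DataFrame, sp1: str, sp2: str, stations: pd.DataFrame,
               config: AnalysisConfig) -> CoUseResult:
    """Run the co-use contrast for the ordered pair (sp1, sp2)."""
    if sp1 == sp2:
        raise ValidationError("sp1 and sp2 must differ")
    part = partition_stations(visits, sp2, stations, config.scope)
    counts = station_counts(visits, sp1, stations, config.scope)
    pv_ids = sorted(part.pv)
    pnv_ids = sorted(part.pnv)
    y_pv = counts.loc[pv_ids].to_numpy(float)
    y_pnv = counts.loc[pnv_ids].to_numpy(float)
    mean_pv = float(y_pv.mean()) if y_pv.size else float("nan")
    mean_pnv = float(y_pnv.mean()) if y_pnv.size else float("nan")
    if y_pnv.size and mean_pnv > 0:
        ratio = mean_pv / mean_pnv
    elif y_pv.size and mean_pv > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    off_pv = off_pnv = None
    if config.effort_offset:
        eff = effort_days(stations.loc[stations["valid"]])
        off_pv = np.log(eff.loc[pv_ids].to_numpy(float))
        off_pnv = np.log(eff.loc[pnv_ids].to_numpy(float))
    try:
        coef, se, p = poisson_contrast(y_pv, y_pnv, off_pv, off_pnv)
    except NotEstimableError:
        return CoUseResult(sp1, sp2, y_pv.size, y_pnv.size, mean_pv, mean_pnv,
                           ratio, float("nan"), float("nan"), float("nan"),
                           CLASS_NOT_ESTIMABLE)
    if p < config.alpha and mean_pv > mean_pnv:
        cls = CLASS_ATTRACTION
    elif p < config.alpha and mean_pv < mean_pnv:
        cls = CLASS_AVOIDANCE
    else:
        cls = CLASS_NONE
    return CoUseResult(sp1, sp2, y_pv.size, y_pnv.size, mean_pv, mean_pnv,
                       ratio, coef, se, p, cls)


def crop_correlation(per_station_counts, crop_sizes):
    """Pearson correlation between visitation and crop size.

    Returns ``(r, p_value)`` with the two-sided t-test p-value. Raises
    :class:`UndefinedCorrelationError` when either vector is constant.
    """
    x = np.asarray(per_station_counts, dtype=float)
    y = np.asarray(crop_sizes, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def all_pairs_couse(visits: pd.DataFrame, stations: pd.DataFrame,
                    config: AnalysisConfig, species=None,
                    bh_adjust: bool = False) -> pd.DataFrame:
    """Co-use contrast for every ordered species pair, both orders.

    With ``bh_adjust`` a Benjamini-Hochberg adjusted p-value column is
    added (classification still uses the raw p, as in the default
    uncorrected analysis).
    """
    sub = scope_visits(visits, config.scope)
    if species is None:
        species = sorted(sub["species"].unique())
    rows = []
    for sp1 in species:
        for sp2 in species:
            if sp1 == sp2:
                continue
            r = couse_test(visits, sp1, sp2, stations, config)
            rows.append({
                "sp1": r.sp1, "sp2": r.sp2, "scope": config.scope,
                "n_PV": r.n_pv, "n_PNV": r.n_pnv,
                "mean_PV": r.mean_pv, "mean_PNV": r.mean_pnv,
                "ratio": r.ratio, "coefficient": r.coefficient,
                "se": r.std_error, "p_value": r.p_value,
                "classification": r.classification,
            })
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_value_bh"] = adj
    return out
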