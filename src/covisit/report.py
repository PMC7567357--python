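"""Human-readable summaries of pipeline result tables."""
from __future__ import annotations

import pandas as pd

from .errors import ValidationError

FUNCTIONAL_GROUPS = {
    "legitimate_disperser": "carnivores / legitimate dispersers",
    "seed_predator": "ungulate seed predators",
    "pulp_feeder": "pulp feeders",
    "mixed": "mixed / unassigned",
}


def visit_totals(visits: pd.DataFrame, roles: pd.DataFrame | None = None) -> pd.DataFrame:
    """Total visits and interactions per species (and functional group)."""
    if len(visits) == 0:
        return pd.DataFrame(columns=["species", "visits", "interactions"])
    tot = (visits.groupby("species")
                 .agg(visits=("species", "size"),
                      interactions=("interaction", "sum"))
                 .reset_index())
    if roles is not None and len(roles):
        role_map = roles.drop_duplicates("species").set_index("species")["role"]
        tot["functional_group"] = tot["species"].map(role_map).fillna("mixed")
    return tot.sort_values("visits", ascending=False).reset_index(drop=True)


def _fmt_table(df: pd.DataFrame) -> str:
    if len(df) == 0:
        return "_no eligible pairs_"
    return "```\n" + df.to_string(index=False, float_format="%.3g") + "\n```"


def consistency_flags(temporal: pd.DataFrame) -> pd.DataFrame:
    """Pairs whose classification differs between the 5- and 30-min windows."""
    if "window_minutes" not in temporal or temporal["window_minutes"].nunique() < 2:
        return pd.DataFrame(columns=["sp_first", "sp_second", "model", "scope"])
    piv = temporal.pivot_table(index=["sp_first", "sp_second", "model", "scope"],
                               columns="window_minutes",
                               values="classification", aggfunc="first")
    differing = piv[piv.nunique(axis=1) > 1]
    return differing.reset_index()


def summarize(temporal: pd.DataFrame | None = None,
              couse: pd.DataFrame | None = None,
              visits: pd.DataFrame | None = None,
              pathways: pd.DataFrame | None = None,
              roles: pd.DataFrame | None = None) -> str:
    """Markdown report across models, windows and scopes."""
    parts = ["# Co-visitation analysis summary", ""]
    if visits is not None:
        parts += ["## Visit totals by species", "",
                  _fmt_table(visit_totals(visits, roles)), ""]
    if couse is not None:
        sig = couse[couse["classification"].isin(["attraction", "avoidance"])]
        parts += ["## Spatial co-use (PV vs PNV Poisson contrast)", "",
                  _fmt_table(sig), ""]
    if temporal is not None:
        if len(temporal) == 0:
            parts += ["## Temporal null models", "", "_no eligible pairs_", ""]
        for model, sub in temporal.groupby("model"):
            label = ("station-pair null" if str(model) == "2"
                     else "occurrence-permutation null")
            sig = sub[sub["classification"].isin(["attraction", "aversion"])]
            cols = ["sp_first", "sp_second", "scope", "window_minutes",
                    "OMTD", "n_obs", "lower_95", "upper_95", "classification"]
            cols = [c for c in cols if c in sig.columns]
            parts += [f"## Temporal null model {model} ({label})", "",
                      _fmt_table(sig[cols]), ""]
        flags = consistency_flags(temporal)
        if len(flags):
            parts += ["## Window-consistency flags (5 vs 30 min differ)", "",
                      _fmt_table(flags), ""]
    if pathways is not None:
        parts += ["## Indirect pathways", "", _fmt_table(pathways), ""]
    return "\n".join(parts)


def summarize_files(paths: dict) -> str:
    """Summarize from result files; raises naming any missing file."""
    import os

    frames = {}
    for key, path in paths.items():
        if path is None:
            frames[key] = None
            continue
        if not os.path.exists(path):
            raise ValidationError(f"missing result file: {path}")
        df = pd.read_csv(path)
        frames[key] = df
    return summarize(**frames)
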