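"""Signed direct and indirect interaction pathways.

Significant pairwise results become signed species-to-species edges
(attraction +1, aversion/avoidance -1); each species gets a signed edge
to every plant it consumes, determined by its functional role
(legitimate seed disperser +1; seed predator and pulp feeder -1, the
latter overridable since e.g. lagomorphs may occasionally disperse).
An indirect effect of species A on a plant via species B is the 2-edge
path A -> B -> plant with sign equal to the product of the edge signs:
e.g. a seed predator that attracts a legitimate disperser has an
indirect *positive* effect on the plant's reproductive success, and a
pulp feeder that repels a seed predator likewise.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

BASIS_TEMPORAL = "temporal_null"
BASIS_COUSE = "spatial_couse"
BASIS_ROLE = "functional_role"

ROLE_SIGNS = {
    "legitimate_disperser": +1,
    "seed_predator": -1,
    "pulp_feeder": -1,
    "mixed": -1,
}
_POSITIVE = {"attraction"}
_NEGATIVE = {"aversion", "avoidance"}


@dataclass(frozen=True)
class DirectEdge:
    source: str
    target: str  # species, or a plant id for role edges
    sign: int
    basis: str


@dataclass(frozen=True)
class IndirectEffect:
    source: str
    plant: str
    via: str
    sign: int


def _sign_of(classification: str) -> int | None:
    if classification in _POSITIVE:
        return +1
    if classification in _NEGATIVE:
        return -1
    return None


def read_roles(path) -> pd.DataFrame:
    """roles.csv: species, plant, role[, sign] (sign overrides the role)."""
    df = pd.read_csv(path)
    missing = [c for c in ("species", "plant", "role") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = ~df["role"].isin(ROLE_SIGNS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown roles {sorted(df.loc[bad, 'role'].unique())}")
    return df


def build_direct_graph(temporal_results: pd.DataFrame | None,
                       couse_results: pd.DataFrame | None,
                       roles: pd.DataFrame) -> list[DirectEdge]:
    """Compose significant pairwise results and roles into signed edges.

    Temporal edges point sp_first -> sp_second (the earlier species
    alters the later one's visitation); co-use edges point sp2 -> sp1
    (sp2's presence at a station alters sp1's station use). Results
    from different bases are kept as separate edges, never merged.
    Raises if a species in a significant result lacks a role row.
    """
    edges: list[DirectEdge] = []
    species_seen: set[str] = set()
    if temporal_results is not None and len(temporal_results):
        for row in temporal_results.itertuples():
            sign = _sign_of(row.classification)
            if sign is None:
                continue
            edges.append(DirectEdge(row.sp_first, row.sp_second, sign,
                                    BASIS_TEMPORAL))
            species_seen |= {row.sp_first, row.sp_second}
    if couse_results is not None and len(couse_results):
        for row in couse_results.itertuples():
            sign = _sign_of(row.classification)
            if sign is None:
                continue
            edges.append(DirectEdge(row.sp2, row.sp1, sign, BASIS_COUSE))
            species_seen |= {row.sp1, row.sp2}
    undefined = species_seen - set(roles["species"])
    if undefined:
        raise ValidationError(
            f"no functional role defined for species: {sorted(undefined)}")
    # drop duplicate species->species edges from the same basis
    edges = list(dict.fromkeys(edges))
    for row in roles.itertuples():
        sign = int(getattr(row, "sign", float("nan"))) \
            if hasattr(row, "sign") and pd.notna(row.sign) else ROLE_SIGNS[row.role]
        edges.append(DirectEdge(row.species, row.plant, sign, BASIS_ROLE))
    return edges


def infer_indirect(edges: list[DirectEdge]) -> list[IndirectEffect]:
    """All 2-edge paths species -> species -> plant, sign = product."""
    role_edges = [e for e in edges if e.basis == BASIS_ROLE]
    inter_edges = [e for e in edges if e.basis != BASIS_ROLE]
    plant_sign = {}
    for e in role_edges:
        plant_sign.setdefault(e.source, {})[e.target] = e.sign
    out = []
    for e in inter_edges:
        for plant, psign in plant_sign.get(e.target, {}).items():
            out.append(IndirectEffect(e.source, plant, e.target,
                                      e.sign * psign))
    return list(dict.fromkeys(out))


def pathways_table(edges: list[DirectEdge]) -> pd.DataFrame:
    """Flat table: one row per 2-edge pathway, tagged by the edge basis."""
    plant_sign = {}
    for e in edges:
        if e.basis == BASIS_ROLE:
            plant_sign.setdefault(e.source, {})[e.target] = e.sign
    rows = []
    for e in edges:
        if e.basis == BASIS_ROLE:
            continue
        for plant, psign in plant_sign.get(e.target, {}).items():
            rows.append({"source": e.source, "via": e.target, "plant": plant,
                         "direct_sign": e.sign,
                         "indirect_sign": e.sign * psign, "basis": e.basis})
    return pd.DataFrame(rows, columns=["source", "via", "plant", "direct_sign",
                                       "indirect_sign", "basis"])


def to_dot(edges: list[DirectEdge]) -> str:
    """Graphviz DOT export of the direct graph (solid +, dashed -)."""
    lines = ["digraph pathways {"]
    for e in edges:
        style = "solid" if e.sign > 0 else "dashed"
        label = "+" if e.sign > 0 else "-"
        lines.append(f'  "{e.source}" -> "{e.target}" '
                     f'[style={style}, label="{label}", comment="{e.basis}"];')
    lines.append("}")
    return "\n".join(lines)
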