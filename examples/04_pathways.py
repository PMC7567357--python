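"""Indirect effects on plant reproductive success.

Significant pairwise interactions are composed with functional roles
into signed two-step pathways species -> species -> plant. A seed
predator (cow, direct - on the plant) that attracts a legitimate
disperser (red fox, direct +) exerts an indirect *positive* effect on
the plant; a pulp feeder that repels a seed predator does too.
"""
import pandas as pd

from covisit import build_direct_graph, infer_indirect, pathways_table, to_dot

temporal = pd.DataFrame([
    {"sp_first": "cow", "sp_second": "red_fox",
     "classification": "attraction"},
    {"sp_first": "lagomorph", "sp_second": "red_deer",
     "classification": "aversion"},
])
roles = pd.DataFrame([
    {"species": "cow", "plant": "dwarf_palm", "role": "seed_predator"},
    {"species": "red_fox", "plant": "dwarf_palm",
     "role": "legitimate_disperser"},
    {"species": "lagomorph", "plant": "dwarf_palm", "role": "pulp_feeder"},
    {"species": "red_deer", "plant": "dwarf_palm", "role": "seed_predator"},
])

edges = build_direct_graph(temporal, None, roles)
print("direct edges (sign +1 helps the plant or draws the partner in):")
for e in edges:
    print(f"  {e.source} -> {e.target}: {e.sign:+d} ({e.basis})")
print()
print("indirect pathways (sign = product along the 2-edge path):")
print(pathways_table(edges).to_string(index=False))
print()
print("Both indirect signs are positive: attracting a disperser, or")
print("repelling a predator, ultimately favours the plant.")
print()
print(to_dot(edges))
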