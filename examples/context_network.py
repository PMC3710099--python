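"""Build the domain context network (fusion + neighbourhood edges),
collapse it by functional category and lay it out for Cytoscape."""

from hepnscape.context_network import (
    build_network,
    collapse_by_category,
    export_graph,
    layout_spring,
    total_weight,
)
from hepnscape.neighborhood import Operon

architectures = {
    "g1": "MNT+HEPN",                    # fusion protein
    "g2": "MNT", "g3": "HEPN",           # a dyad operon
    "g4": "methylase", "g5": "REase", "g6": "HEPN",   # R-M-linked operon
}
operons = [
    Operon("op1", "ctg", "+", ("g2", "g3"), (0, 1)),
    Operon("op2", "ctg", "+", ("g4", "g5", "g6"), (0, 1)),
]
g = build_network(architectures, operons)
for u, v, k, d in sorted(g.edges(keys=True, data=True)):
    print(f"{u} -- {v}  [{d['type']}]  weight {d['weight']}")
# fusion edges come from adjacent domains in one polypeptide; neighbourhood
# edges link domains carried by different genes of the same operon.

collapsed = collapse_by_category(
    g, {"MNT": "TA", "HEPN": "TA", "methylase": "R-M", "REase": "R-M"}
)
print("total weight before/after collapse:",
      total_weight(g), "/", total_weight(collapsed))

export_graph(g, "context.graphml", "graphml")
pos = layout_spring(g, seed=0)
print("layout of", len(pos), "nodes; HEPN at "
      f"({pos['HEPN'][0]:.2f}, {pos['HEPN'][1]:.2f})")
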