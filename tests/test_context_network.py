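"""Domain context network construction, collapsing, export and layout."""

import math

import networkx as nx
import pytest

from oracles import recount_fusion_weight, recount_neighborhood_weight
from hepnscape.context_network import (
    build_network,
    collapse_by_category,
    export_graph,
    layout_spring,
    total_weight,
)
from hepnscape.neighborhood import Operon


def _op(opid, genes, strand="+"):
    return Operon(opid, "ctg", strand, tuple(genes), (0, 1))


def test_fusion_edges_only_adjacent():
    g = build_network({"p1": "A+B+C"}, [])
    edges = {(u, v, k): d["weight"] for u, v, k, d in g.edges(keys=True, data=True)}
    assert edges == {("A", "B", "fusion"): 1, ("B", "C", "fusion"): 1}
    assert not g.has_edge("A", "C")


def test_neighborhood_edges_cross_gene():
    g = build_network({"g1": "A", "g2": "D"}, [_op("op1", ["g1", "g2"])])
    edges = {(u, v, k): d["weight"] for u, v, k, d in g.edges(keys=True, data=True)}
    assert edges == {("A", "D", "neighborhood"): 1}
    # unknown-architecture gene becomes an "unknown" node
    g = build_network({"g1": "A"}, [_op("op1", ["g1", "gX"])])
    assert g.has_edge("A", "unknown", key="neighborhood")


def test_empty_input():
    g = build_network({}, [])
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0


def test_weight_aggregation_and_recount():
    """Edge weights count supporting instances; totals match independent
    brute-force recounts of proteins and operons."""
    archs = {
        "g1": "MNT+HEPN",
        "g2": "MNT+HEPN",
        "g3": "HEPN",
        "g4": "methylase+REase+helicase",
        "g5": "REase",
        "g6": "HEPN+HEPN",
    }
    operons = [
        _op("op1", ["g3", "g5"]),
        _op("op2", ["g1", "g5"]),
        _op("op3", ["g2", "g3", "g4"]),
    ]
    g = build_network(archs, operons)
    assert g["HEPN"]["MNT"]["fusion"]["weight"] == 2
    assert total_weight(g, "fusion") == recount_fusion_weight(archs)
    assert total_weight(g, "neighborhood") == recount_neighborhood_weight(
        archs, operons
    )
    # repeated pair inside one protein counts once per protein
    assert g["HEPN"]["HEPN"]["fusion"]["weight"] == 1


def test_collapse_conserves_weight():
    archs = {"g1": "methylase+HEPN", "g2": "REase+HEPN"}
    operons = [_op("op1", ["g1", "g2"])]
    g = build_network(archs, operons)
    cmap = {"methylase": "R-M", "REase": "R-M", "HEPN": "TA"}
    c = collapse_by_category(g, cmap)
    assert total_weight(c) == total_weight(g)
    # the two domain->HEPN fusion edges merge into one category edge
    assert c["R-M"]["TA"]["fusion"]["weight"] == 2
    # identity map leaves the graph unchanged
    ident = collapse_by_category(g, {n: n for n in g.nodes})
    assert nx.utils.graphs_equal(ident, g) or (
        sorted(ident.edges(keys=True)) == sorted(g.edges(keys=True))
    )
    # all nodes in one category -> a single node with self-loops
    single = collapse_by_category(g, {n: "all" for n in g.nodes})
    assert list(single.nodes) == ["all"]
    assert total_weight(single) == total_weight(g)


def test_export_graphml_roundtrip(tmp_path):
    g = build_network({"p1": "A+B"}, [_op("op1", ["p1", "p2"])])
    p = tmp_path / "g.graphml"
    export_graph(g, p, "graphml")
    back = nx.read_graphml(p)
    assert sorted(back.nodes) == sorted(g.nodes)
    for u, v, k, d in g.edges(keys=True, data=True):
        assert back.has_edge(u, v)
        cand = back[u][v]
        if back.is_multigraph():
            datas = list(cand.values())
        else:
            datas = [cand]
        match = [dd for dd in datas
                 if dd["type"] == d["type"] and int(dd["weight"]) == d["weight"]]
        assert match


def test_export_sif_and_tsv(tmp_path):
    g = build_network({"p1": "A+B"}, [_op("op1", ["p1", "p2"])])
    sif = tmp_path / "g.sif"
    export_graph(g, sif, "sif")
    lines = sif.read_text().splitlines()
    assert len(lines) == g.number_of_edges()
    assert all(line.split("\t")[1] in {"fusion", "neighborhood"} for line in lines)
    tsv = tmp_path / "g.tsv"
    export_graph(g, tsv, "edge-tsv")
    assert len(tsv.read_text().splitlines()) == g.number_of_edges() + 1
    with pytest.raises(ValueError, match="unknown export format"):
        export_graph(g, tmp_path / "x", "dot")
    # empty graph exports are valid documents
    export_graph(nx.MultiGraph(), tmp_path / "e.graphml", "graphml")
    assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0


def test_layout_spring():
    g = nx.MultiGraph()
    g.add_node("solo")
    pos = layout_spring(g)
    assert pos["solo"] == (0.0, 0.0)
    g2 = nx.MultiGraph()
    g2.add_edge("x", "y", key="fusion", type="fusion", weight=1)
    p = layout_spring(g2, seed=1)
    sep = math.dist(p["x"], p["y"])
    assert 0.5 <= sep <= 2.0  # near the Kamada-Kawai target edge length
    assert layout_spring(g2, seed=1) == p  # deterministic
    # disconnected components land in distinct grid cells
    g2.add_edge("a", "b", key="fusion", type="fusion", weight=1)
    p = layout_spring(g2)
    assert math.dist(p["a"], p["x"]) > 1.0
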