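"""Domain context networks: fusion and gene-neighbourhood edges.

Nodes are domain names.  Two typed edge classes mirror the two kinds of
contextual association: ``fusion`` edges join domains adjacent in the
same polypeptide (weight = number of distinct supporting proteins) and
``neighborhood`` edges join domains carried by *different* genes of the
same predicted operon (weight = number of distinct supporting operons).
Edges are undirected with lexicographically canonicalised endpoints; the
N->C orientation of fusion pairs is retained as an edge attribute.  The
graph container is a :class:`networkx.MultiGraph` keyed by edge type, so
a fusion and a neighbourhood edge can coexist between one node pair.
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from hepnscape.architecture import Architecture, fusion_pairs
from hepnscape.neighborhood import Operon

FUSION = "fusion"
NEIGHBORHOOD = "neighborhood"


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_network(
    architectures: Mapping[str, Architecture | str],
    operons: Sequence[Operon] = (),
) -> nx.MultiGraph:
    """Build the typed, weighted domain context graph.

    ``architectures`` maps gene/protein id -> :class:`Architecture` (or
    architecture string).  A gene referenced by an operon but absent
    from ``architectures`` contributes the node "unknown".  A domain
    pair repeated within one protein (or operon) supports its edge once;
    weights count supporting instances, not pair multiplicity.
    """
    g = nx.MultiGraph()

    def domains_of(gene_id: str) -> tuple[str, ...]:
        arch = architectures.get(gene_id)
        if arch is None:
            return ("unknown",)
        if isinstance(arch, Architecture):
            return arch.domains if arch.domains else ("unknown",)
        return tuple(arch.split("+")) if arch and arch != "unknown" else ("unknown",)

    for gene_id in sorted(architectures):
        arch = architectures[gene_id]
        pairs = fusion_pairs(arch)
        seen = set()
        for a, b in pairs:
            key = _canon(a, b)
            orientation = f"{a}>{b}"
            if key in seen:
                continue
            seen.add(key)
            if g.has_edge(*key, key=FUSION):
                g[key[0]][key[1]][FUSION]["weight"] += 1
            else:
                g.add_edge(
                    *key, key=FUSION, type=FUSION, weight=1, orientation=orientation
                )
    for op in operons:
        per_gene = [domains_of(gid) for gid in op.gene_ids]
        seen = set()
        for (i, doms_i), (j, doms_j) in itertools.combinations(
            enumerate(per_gene), 2
        ):
            for a in doms_i:
                for b in doms_j:
                    key = _canon(a, b)
                    if key in seen:
                        continue
                    seen.add(key)
                    if g.has_edge(*key, key=NEIGHBORHOOD):
                        g[key[0]][key[1]][NEIGHBORHOOD]["weight"] += 1
                    else:
                        g.add_edge(
                            *key, key=NEIGHBORHOOD, type=NEIGHBORHOOD, weight=1
                        )
    # isolated nodes for single-domain proteins keep the node set complete
    for gene_id in sorted(architectures):
        for d in domains_of(gene_id):
            if d != "unknown" and d not in g:
                g.add_node(d)
    return g


def collapse_by_category(
    graph: nx.MultiGraph, category_map: Mapping[str, str]
) -> nx.MultiGraph:
    """Collapse domain nodes into functional categories.

    Unmapped domains go to category "other".  Parallel edges of the same
    type merge with summed weights; edges inside one category become
    self-loops.  Total edge weight is conserved.
    """
    out = nx.MultiGraph()
    for node, data in graph.nodes(data=True):
        cat = category_map.get(node, "other")
        if cat not in out:
            out.add_node(cat)
    for u, v, key, data in graph.edges(keys=True, data=True):
        cu = category_map.get(u, "other")
        cv = category_map.get(v, "other")
        a, b = _canon(cu, cv)
        if out.has_edge(a, b, key=key):
            out[a][b][key]["weight"] += data.get("weight", 1)
        else:
            out.add_edge(a, b, key=key, type=data.get("type", key),
                         weight=data.get("weight", 1))
    return out


def total_weight(graph: nx.MultiGraph, edge_type: str | None = None) -> int:
    """Sum of edge weights, optionally restricted to one edge type."""
    return sum(
        d.get("weight", 1)
        for _, _, k, d in graph.edges(keys=True, data=True)
        if edge_type is None or d.get("type", k) == edge_type
    )


def export_graph(graph: nx.MultiGraph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network for external viewers (e.g. Cytoscape).

    Formats: ``graphml`` (typed/weighted attributes round-trip),
    ``sif`` (edge type as the interaction label) and ``edge-tsv``.
    Node and edge order is sorted, so output is bit-reproducible.
    """
    path = Path(path)
    edges = sorted(
        (
            (u, v, d.get("type", k), d.get("weight", 1))
            for u, v, k, d in graph.edges(keys=True, data=True)
        ),
        key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2]),
    )
    if fmt == "graphml":
        g2 = nx.MultiGraph()
        g2.add_nodes_from(sorted(graph.nodes()))
        for u, v, t, w in edges:
            g2.add_edge(u, v, key=t, type=t, weight=w)
        nx.write_graphml(g2, str(path))
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, t, _ in edges:
                a, b = _canon(u, v)
                fh.write(f"{a}\t{t}\t{b}\n")
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\ttype\tweight\n")
            for u, v, t, w in edges:
                a, b = _canon(u, v)
                fh.write(f"{a}\t{b}\t{t}\t{w}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def layout_spring(graph: nx.MultiGraph, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Deterministic Kamada-Kawai spring-embedded coordinates.

    Each connected component is laid out independently (the Kamada-Kawai
    objective is defined on graph distances) and components are placed
    on a grid.  A single node sits at the origin of its cell; the first
    component's cell is at the origin.  ``seed`` is accepted for
    interface stability; the layout itself is deterministic.
    """
    simple = nx.Graph()
    simple.add_nodes_from(sorted(graph.nodes()))
    for u, v in graph.edges():
        simple.add_edge(u, v)
    components = sorted(nx.connected_components(simple), key=lambda c: min(c))
    pos: dict[str, tuple[float, float]] = {}
    ncols = max(1, math.ceil(math.sqrt(len(components))))
    cell = 4.0  # grid pitch; KK coordinates are scaled to ~unit edge length
    for idx, comp in enumerate(components):
        ox = (idx % ncols) * cell
        oy = (idx // ncols) * cell
        nodes = sorted(comp)
        if len(nodes) == 1:
            pos[nodes[0]] = (ox, oy)
            continue
        sub = simple.subgraph(nodes)
        p = nx.kamada_kawai_layout(sub, scale=len(nodes) / 4.0)
        for node, (x, y) in p.items():
            pos[node] = (ox + float(x), oy + float(y))
    return pos
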