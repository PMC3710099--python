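"""End-to-end neighbourhood analysis and planted-truth evaluation.

``run_pipeline`` chains the stages on one annotated contig: operon and
divergon prediction, per-protein domain annotation, TA-dyad detection,
fusion identification and context-network construction.
``evaluate_recovery`` scores a run against a synthetic truth table.

Recovery semantics (noise-free setting): dyads, divergons and fusion
calls are scored against *all* predictions of their type, since the
background cannot generate them; operon recovery is scored on the
predicted operons that touch planted multi-gene operon elements,
because background genes legitimately form (unlabelled) operons of
their own under the intergenic-distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from hepnscape.architecture import (
    Architecture,
    DomainLibrary,
    DomainLibraryEntry,
    annotate_protein,
    architecture_string,
)
from hepnscape.context_network import build_network
from hepnscape.genome_io import ContigRecord
from hepnscape.neighborhood import (
    DEFAULT_MAX_GAP,
    DEFAULT_MAX_HEAD_GAP,
    Divergon,
    Operon,
    find_divergons,
    predict_operons,
)
from hepnscape.synthetic_data import TruthTable, sentinel_sequence
from hepnscape.ta_detector import TADyad, detect_ta_dyads


def sentinel_library(domain_labels) -> DomainLibrary:
    """A sentinel-detector library for the given domain names (the
    detector form planted by the synthetic generator)."""
    return DomainLibrary(
        entries=[
            DomainLibraryEntry(
                name=lab, detector="sentinel", sentinel=sentinel_sequence(lab)
            )
            for lab in sorted(set(domain_labels))
        ]
    )


@dataclass
class PipelineResult:
    contig_id: str
    operons: list[Operon]
    divergons: list[Divergon]
    architectures: dict[str, Architecture]
    dyads: list[TADyad]
    #: gene ids of proteins carrying >= 2 annotated domains
    fusion_genes: list[str]
    network: nx.MultiGraph = field(repr=False, default=None)


def run_pipeline(
    contig: ContigRecord,
    library: DomainLibrary,
    max_gap: int = DEFAULT_MAX_GAP,
    max_head_gap: int = DEFAULT_MAX_HEAD_GAP,
    toxin_domains=frozenset({"HEPN"}),
    antitoxin_domains=frozenset({"MNT"}),
) -> PipelineResult:
    """Run the full neighbourhood-analysis chain on one contig."""
    operons = predict_operons(contig, max_gap=max_gap)
    divergons = find_divergons(contig, max_head_gap=max_head_gap)
    architectures: dict[str, Architecture] = {}
    for g in contig.genes:
        if not g.protein_seq:
            architectures[g.gene_id] = Architecture(g.gene_id, ())
            continue
        anns = annotate_protein(g.protein_seq, library, protein_id=g.gene_id)
        architectures[g.gene_id] = Architecture(
            g.gene_id, tuple(a.domain_name for a in sorted(anns, key=lambda a: a.start))
        )
    dyads = detect_ta_dyads(
        operons, architectures, contig,
        toxin_domains=toxin_domains, antitoxin_domains=antitoxin_domains,
    )
    fusion_genes = sorted(
        gid for gid, arch in architectures.items() if len(arch.domains) >= 2
    )
    network = build_network(architectures, operons)
    return PipelineResult(
        contig_id=contig.contig_id,
        operons=operons,
        divergons=divergons,
        architectures=architectures,
        dyads=dyads,
        fusion_genes=fusion_genes,
        network=network,
    )


def _prf(matched: int, n_pred: int, n_truth: int) -> dict[str, float]:
    precision = matched / n_pred if n_pred else 1.0
    recall = matched / n_truth if n_truth else 1.0
    return {"precision": precision, "recall": recall,
            "matched": matched, "predicted": n_pred, "planted": n_truth}


def evaluate_recovery(result: PipelineResult, truth: TruthTable) -> dict:
    """Precision/recall of planted-element recovery for one contig."""
    out: dict[str, dict] = {}

    # --- operons: exact gene-set match, scored on predictions touching truth
    planted_ops = {eid: gids for eid, gids in truth.of_kind("operon").items()}
    planted_sets = {gids: eid for eid, gids in planted_ops.items()}
    touching = [
        op for op in result.operons
        if any(
            truth.genes[g].element_id in planted_ops
            for g in op.gene_ids if g in truth.genes
        )
    ]
    matched = sum(1 for op in touching if op.gene_ids in planted_sets)
    out["operons"] = _prf(matched, len(touching), len(planted_ops))

    # --- TA dyads: correct gene pair, roles and orientation
    planted_dyads = truth.of_kind("ta_dyad")
    dyad_truth = {
        (gids[0], gids[1]): eid for eid, gids in planted_dyads.items()
    }  # (antitoxin 5', toxin 3')
    matched = sum(
        1 for d in result.dyads
        if (d.antitoxin_candidate_gene, d.toxin_candidate_gene) in dyad_truth
        and d.orientation == "canonical"
    )
    out["dyads"] = _prf(matched, len(result.dyads), len(planted_dyads))

    # --- divergons: exact (left, right) gene pair
    planted_div = {tuple(gids) for gids in truth.of_kind("divergon").values()}
    matched = sum(
        1 for d in result.divergons
        if (d.left_gene_id, d.right_gene_id) in planted_div
    )
    out["divergons"] = _prf(matched, len(result.divergons), len(planted_div))

    # --- fusions: exact N->C domain list on exactly the planted genes
    planted_fusions = {
        gids[0]: truth.genes[gids[0]].domains
        for gids in truth.of_kind("fusion").values()
    }
    matched = sum(
        1 for gid in result.fusion_genes
        if planted_fusions.get(gid) == result.architectures[gid].domains
    )
    out["fusions"] = _prf(matched, len(result.fusion_genes), len(planted_fusions))
    return out
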