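"""Operon and divergon prediction from gene order, strand and spacing.

An operon is approximated as a maximal run of co-directional genes whose
consecutive intergenic distances do not exceed a threshold (default
100 nt).  This is a distance proxy for co-transcription from a shared
promoter; no promoter sequence model is applied.  Overlapping genes
(negative intergenic distance) always satisfy the rule, since overlap is
stronger evidence of co-transcription than a small gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from hepnscape.genome_io import ContigRecord, GeneRecord

DEFAULT_MAX_GAP = 100  # nt, the operon intergenic-distance criterion
DEFAULT_MAX_HEAD_GAP = 300  # nt, span within which divergent 5' ends may share a promoter


@dataclass(frozen=True)
class Operon:
    """A predicted transcription unit.

    ``gene_ids`` are ordered 5'->3' along the transcript: genomic order
    for '+' strand operons, reversed genomic order for '-' strand.
    ``span`` is the genomic interval covered (0-based half-open).
    """

    operon_id: str
    contig_id: str
    strand: str
    gene_ids: tuple[str, ...]
    span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Divergon:
    """A head-to-head gene pair potentially sharing a bidirectional promoter."""

    left_gene_id: str
    right_gene_id: str
    head_gap: int


def intergenic_distance(g1: GeneRecord, g2: GeneRecord) -> int:
    """Distance in nt between two genes on the same contig.

    ``g1`` must start at or before ``g2``; the result is
    ``g2.start - g1.end`` and is negative when the genes overlap.
    """
    if g1.contig_id != g2.contig_id:
        raise ValueError(
            f"genes {g1.gene_id} and {g2.gene_id} are on different contigs"
        )
    if g1.start > g2.start:
        raise ValueError("g1 must not start after g2")
    return g2.start - g1.end


def predict_operons(
    contig: ContigRecord, max_gap: int = DEFAULT_MAX_GAP
) -> list[Operon]:
    """Partition a contig's genes into predicted operons.

    Consecutive genes join the same operon iff they are co-directional
    and their intergenic distance is <= ``max_gap``.  Every gene belongs
    to exactly one operon (singletons allowed).  On circular contigs a
    run may wrap the origin; it is reported once, anchored at its
    5'-most gene.  Operon ids are assigned in genomic order.
    """
    genes = contig.genes
    if not genes:
        return []
    # maximal runs in genomic order
    runs: list[list[GeneRecord]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        if cur.strand == prev.strand and intergenic_distance(prev, cur) <= max_gap:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    # a run may wrap the origin of a circular contig
    if contig.circular and len(runs) > 1:
        first, last = runs[0], runs[-1]
        wrap_gap = contig.length - last[-1].end + first[0].start
        if first[0].strand == last[-1].strand and wrap_gap <= max_gap:
            runs[0] = last + first
            runs.pop()
    operons = []
    for i, run in enumerate(runs):
        strand = run[0].strand
        ordered = run if strand == "+" else list(reversed(run))
        operons.append(
            Operon(
                operon_id=f"{contig.contig_id}_op{i + 1}",
                contig_id=contig.contig_id,
                strand=strand,
                gene_ids=tuple(g.gene_id for g in ordered),
                span=(min(g.start for g in run), max(g.end for g in run)),
            )
        )
    return operons


def find_divergons(
    contig: ContigRecord, max_head_gap: int = DEFAULT_MAX_HEAD_GAP
) -> list[Divergon]:
    """Find adjacent head-to-head ('-' then '+') gene pairs.

    Only the (-,+) strand pattern puts the two 5' ends face to face;
    the gap between them must be non-negative and <= ``max_head_gap``.
    """
    out = []
    for left, right in zip(contig.genes, contig.genes[1:]):
        if left.strand == "-" and right.strand == "+":
            gap = right.start - left.end
            if 0 <= gap <= max_head_gap:
                out.append(
                    Divergon(
                        left_gene_id=left.gene_id,
                        right_gene_id=right.gene_id,
                        head_gap=gap,
                    )
                )
    return out


def neighborhood(
    contig: ContigRecord, anchor_gene_id: str, k: int
) -> list[GeneRecord]:
    """Up to ``k`` genes on each side of the anchor, in genomic order.

    Truncates at contig ends on linear contigs; wraps around the origin
    on circular ones (never repeating a gene).
    """
    idx = next(
        (i for i, g in enumerate(contig.genes) if g.gene_id == anchor_gene_id),
        None,
    )
    if idx is None:
        raise KeyError(f"no gene {anchor_gene_id!r} on contig {contig.contig_id}")
    n = len(contig.genes)
    if contig.circular:
        picked, seen = [], set()
        for off in range(-min(k, n - 1), min(k, n - 1) + 1):
            j = (idx + off) % n
            if j not in seen:
                seen.add(j)
                picked.append(j)
        return [contig.genes[j] for j in picked]
    lo = max(0, idx - k)
    hi = min(n, idx + k + 1)
    return contig.genes[lo:hi]
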