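"""Toxin-antitoxin dyad detection and defense-context classification.

Type II TA modules are two co-transcribed genes in which the unstable
antitoxin neutralises a stable toxin; the antitoxin gene typically sits
5' of the toxin so that antitoxin is produced first.  In MNT-HEPN dyads
the MNT (minimal nucleotidyltransferase) antitoxin almost always
occupies the 5' position, which is the orientation called ``canonical``
here.  Detection is strict: only two-gene operons qualify as dyads;
larger defense operons (R-M, CRISPR-Cas, Abi, Pgl, TerD contexts) are
handled by :func:`classify_context` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from hepnscape.architecture import Architecture
from hepnscape.genome_io import ContigRecord
from hepnscape.neighborhood import Operon

#: curated domain -> defense-category rules reflecting recurrent
#: neighbourhood associations of HEPN proteins; editable curation,
#: not a computed result.
DEFAULT_CATEGORY_RULES: dict[str, str] = {
    "MNT": "TA",
    "HEPN": "TA",
    "higA": "TA",
    "methylase": "R-M",
    "REase": "R-M",
    "MTase": "R-M",
    "Specificity": "R-M",
    "helicase": "R-M",
    "McrBC": "R-M",
    "Cas2": "CRISPR-Cas",
    "Csx1": "CRISPR-Cas",
    "Csm6": "CRISPR-Cas",
    "CARF": "CRISPR-Cas",
    "AbiEii": "Abi",
    "Abi2": "Abi",
    "PglX": "Pgl",
    "PglY": "Pgl",
    "PglZ": "Pgl",
    "TerD": "TerD",
}


@dataclass(frozen=True)
class TADyad:
    """A candidate two-gene toxin-antitoxin module."""

    operon_id: str
    antitoxin_candidate_gene: str  # gene carrying the antitoxin-set domain
    toxin_candidate_gene: str
    orientation: str  # canonical (antitoxin 5') or inverted
    gap_nt: int


@dataclass(frozen=True)
class ContextCall:
    """Defense-category classification of one operon."""

    operon_id: str
    category: str
    evidence: tuple[str, ...]
    tie: bool = False


def _domains_of(
    gene_id: str, architectures: Mapping[str, Architecture | str]
) -> tuple[str, ...]:
    arch = architectures.get(gene_id)
    if arch is None:
        return ()
    if isinstance(arch, Architecture):
        return arch.domains
    return () if arch == "unknown" else tuple(arch.split("+"))


def detect_ta_dyads(
    operons: Sequence[Operon],
    architectures: Mapping[str, Architecture | str],
    contig: ContigRecord,
    toxin_domains: set[str] = frozenset({"HEPN"}),
    antitoxin_domains: set[str] = frozenset({"MNT"}),
) -> list[TADyad]:
    """Find candidate TA dyads among two-gene operons.

    A dyad is called when one gene of a two-gene operon carries a
    toxin-set domain and the other an antitoxin-set domain (a gene
    carrying both sets can serve as either role, but the two roles must
    fall on different genes).  Orientation is ``canonical`` iff the
    antitoxin gene is 5' in the operon's own strand frame — not genomic
    left/right, so the call is invariant to contig orientation.
    """
    toxin_domains = set(toxin_domains)
    antitoxin_domains = set(antitoxin_domains)
    dyads = []
    for op in operons:
        if len(op.gene_ids) != 2:
            continue
        g5, g3 = op.gene_ids  # already 5'->3'
        d5 = set(_domains_of(g5, architectures))
        d3 = set(_domains_of(g3, architectures))
        assignments = []
        if d5 & antitoxin_domains and d3 & toxin_domains:
            assignments.append((g5, g3, "canonical"))
        if d5 & toxin_domains and d3 & antitoxin_domains:
            assignments.append((g3, g5, "inverted"))
        if not assignments:
            continue
        # a gene pair matching both ways (both genes carry both sets) is
        # reported once, preferring the canonical reading
        anti, tox, orientation = assignments[0]
        a, b = contig.gene(g5), contig.gene(g3)
        left, right = (a, b) if a.start <= b.start else (b, a)
        dyads.append(
            TADyad(
                operon_id=op.operon_id,
                antitoxin_candidate_gene=anti,
                toxin_candidate_gene=tox,
                orientation=orientation,
                gap_nt=right.start - left.end,
            )
        )
    return dyads


def classify_context(
    operon: Operon,
    architectures: Mapping[str, Architecture | str],
    category_rules: Mapping[str, str] | None = None,
) -> ContextCall:
    """Assign an operon to a defense category by its member domains.

    Each member domain matching a rule votes for its category; the
    majority category wins, ties break to the lexicographically smaller
    category and are flagged.  No matching domain -> "other".
    """
    rules = DEFAULT_CATEGORY_RULES if category_rules is None else category_rules
    votes: dict[str, list[str]] = {}
    for gid in operon.gene_ids:
        for dom in _domains_of(gid, architectures):
            cat = rules.get(dom)
            if cat is not None:
                votes.setdefault(cat, []).append(dom)
    if not votes:
        return ContextCall(operon.operon_id, "other", (), tie=False)
    best_n = max(len(v) for v in votes.values())
    winners = sorted(c for c, v in votes.items() if len(v) == best_n)
    category = winners[0]
    return ContextCall(
        operon_id=operon.operon_id,
        category=category,
        evidence=tuple(sorted(set(votes[category]))),
        tie=len(winners) > 1,
    )


def orientation_fractions(dyads: Sequence[TADyad]) -> dict[str, float]:
    """Fraction of dyads in each orientation (the paper's 'almost always
    5'' observation is reported as a fraction, not asserted)."""
    if not dyads:
        return {}
    out: dict[str, int] = {}
    for d in dyads:
        out[d.orientation] = out.get(d.orientation, 0) + 1
    return {k: v / len(dyads) for k, v in sorted(out.items())}
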