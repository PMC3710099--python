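"""Synthetic annotated genomes with planted structures and truth labels.

The generator emulates the features of prokaryotic contigs that the
analysis stages consume: toxin-antitoxin dyads (antitoxin 5'), multi-
gene operons, head-to-head divergons, multidomain fusion proteins and
background genes.  Planted "domains" are fixed sentinel subsequences
(30 residues, derived deterministically from the domain name) so the
architecture module can recover them exactly; there is no evolutionary
sequence simulation.

Layout rules of the stated world:

* gaps inside planted elements are exactly as requested (negative gaps
  down to -50 nt model overlapping genes);
* planted elements are separated from anything else by a large gap
  drawn from 400-1000 nt — beyond both the 100-nt operon criterion and
  the 300-nt divergon window, so element boundaries are unambiguous;
* gaps between background genes come from a two-component mixture
  (20-100 nt and 400-1000 nt) so operon prediction is exercised on the
  background too;
* background genes sit on the '+' strand by default, so the only
  head-to-head arrangements are the planted divergons.

Identical plan + seed gives byte-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from hepnscape.genome_io import (
    Alignment,
    ContigRecord,
    GeneRecord,
    write_fasta,
    write_genbank,
)
from hepnscape.motif_engine import HYDROPHOBIC, POLAR, RESIDUE_CLASSES, SMALL

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet for motif-planting: no R/H (cannot seed a second
#: R-x{4..6}-H site) and no E/K (cannot seed a stray Ex3[KR])
MOTIF_BACKGROUND = "ACDFGILMNPQSTVWY"
#: sentinel alphabet: no R/H so planted domains never mimic the motif
SENTINEL_ALPHABET = "ACDEFGIKLMNPQSTVWY"
SENTINEL_LENGTH = 30

MIN_GAP = -50
MAX_GAP = 5000

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _seed_from(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")


def sentinel_sequence(domain_label: str, length: int = SENTINEL_LENGTH) -> str:
    """Deterministic sentinel subsequence standing in for a domain."""
    rng = np.random.default_rng(_seed_from("sentinel::" + domain_label))
    return "".join(rng.choice(list(SENTINEL_ALPHABET), size=length))


# ---------------------------------------------------------------------------
# plan elements

@dataclass(frozen=True)
class TADyadSpec:
    kind: str = field(default="ta_dyad", init=False)
    antitoxin_label: str = "MNT"
    toxin_label: str = "HEPN"
    gap_nt: int = 30
    strand: str = "+"


@dataclass(frozen=True)
class OperonSpec:
    kind: str = field(default="operon", init=False)
    labels: tuple[str, ...] = ()
    gaps_nt: tuple[int, ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.gaps_nt) != max(len(self.labels) - 1, 0):
            raise ValueError("operon needs len(labels)-1 gaps")


@dataclass(frozen=True)
class DivergonSpec:
    kind: str = field(default="divergon", init=False)
    labels: tuple[str, str] = ("unknownL", "unknownR")
    head_gap_nt: int = 100


@dataclass(frozen=True)
class FusionSpec:
    kind: str = field(default="fusion", init=False)
    domain_labels: tuple[str, ...] = ("MNT", "HEPN")

    def __post_init__(self) -> None:
        if len(self.domain_labels) < 2:
            raise ValueError("fusion needs >= 2 domains")


def ta_dyad(antitoxin_label="MNT", toxin_label="HEPN", gap_nt=30, strand="+"):
    """A two-gene TA module, antitoxin 5' of the toxin (the canonical
    arrangement of MNT-HEPN dyads)."""
    return TADyadSpec(antitoxin_label, toxin_label, gap_nt, strand)


def operon(labels: Sequence[str], gaps_nt: Sequence[int], strand: str = "+"):
    return OperonSpec(tuple(labels), tuple(gaps_nt), strand)


def divergon(labels: Sequence[str] = ("unknownL", "unknownR"), head_gap_nt: int = 100):
    return DivergonSpec(tuple(labels), head_gap_nt)


def fusion_protein(domain_labels: Sequence[str] = ("MNT", "HEPN")):
    return FusionSpec(tuple(domain_labels))


@dataclass
class GenomePlan:
    """Everything that determines a synthetic contig.

    The seed fully determines the output.  ``intergenic_background``
    gives the two mixture components (small, large) as (lo, hi) ranges;
    the small component must stay <= 100 nt and the large one > 100 nt.
    """

    seed: int = 0
    n_background_genes: int = 20
    planted_elements: list = field(default_factory=list)
    small_gap_range: tuple[int, int] = (20, 100)
    large_gap_range: tuple[int, int] = (400, 1000)
    small_gap_weight: float = 0.5
    gene_length_range: tuple[int, int] = (300, 900)  # nt
    background_strand: str = "+"
    contig_id: str = "synctg"
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.small_gap_range[1] <= 100 < self.large_gap_range[0]:
            raise ValueError(
                "background gap mixture must include components <=100 and >100 nt"
            )
        for el in self.planted_elements:
            gaps = []
            if isinstance(el, TADyadSpec):
                gaps = [el.gap_nt]
            elif isinstance(el, OperonSpec):
                gaps = list(el.gaps_nt)
            elif isinstance(el, DivergonSpec):
                gaps = [el.head_gap_nt]
            for g in gaps:
                if not MIN_GAP <= g <= MAX_GAP:
                    raise ValueError(f"planted gap {g} outside [{MIN_GAP}, {MAX_GAP}]")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    element_id: str
    role: str
    domains: tuple[str, ...]


@dataclass
class TruthTable:
    """Machine-readable ground truth for one synthetic contig."""

    genes: dict[str, TruthRecord]
    #: element_id -> (kind, gene_ids); gene ids are 5'->3' for dyads and
    #: operons, genomic left/right for divergons
    elements: dict[str, tuple[str, tuple[str, ...]]]

    def of_kind(self, kind: str) -> dict[str, tuple[str, ...]]:
        return {eid: gids for eid, (k, gids) in self.elements.items() if k == kind}


# ---------------------------------------------------------------------------
# generation

def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(rng.choice(list(AA20), size=n_aa))


def _labelled_protein(rng: np.random.Generator, label: str, n_aa: int) -> str:
    """A protein of ``n_aa`` residues carrying the label's sentinel."""
    pad_total = n_aa - SENTINEL_LENGTH
    if pad_total < 2:
        raise ValueError(f"gene too short for sentinel domain {label!r}")
    left = int(rng.integers(1, pad_total))
    return (
        _random_protein(rng, left)
        + sentinel_sequence(label)
        + _random_protein(rng, pad_total - left)
    )


def _fusion_protein_seq(
    rng: np.random.Generator, labels: Sequence[str], n_aa: int
) -> str:
    need = SENTINEL_LENGTH * len(labels)
    pad_total = n_aa - need
    if pad_total < len(labels) + 1:
        raise ValueError("gene too short for fusion domains")
    # split padding into len(labels)+1 chunks of >= 1 residue
    cuts = sorted(
        rng.choice(np.arange(1, pad_total), size=len(labels), replace=False)
    )
    chunks = np.diff([0, *cuts, pad_total])
    parts = [_random_protein(rng, int(chunks[0]))]
    for lab, chunk in zip(labels, chunks[1:]):
        parts.append(sentinel_sequence(lab))
        parts.append(_random_protein(rng, int(chunk)))
    return "".join(parts)


@dataclass
class _PlannedGene:
    role: str
    element_id: str
    strand: str
    protein: str
    domains: tuple[str, ...]
    gap_before: int | None  # None = background-mixture gap


def _element_genes(
    el, element_id: str, rng: np.random.Generator, aa_range: tuple[int, int]
) -> list[_PlannedGene]:
    def n_aa(min_extra: int = 0) -> int:
        lo = max(aa_range[0], min_extra)
        return int(rng.integers(lo, max(aa_range[1], lo + 1)))

    if isinstance(el, TADyadSpec):
        five = _PlannedGene(
            "antitoxin", element_id, el.strand,
            _labelled_protein(rng, el.antitoxin_label, n_aa(SENTINEL_LENGTH + 2)),
            (el.antitoxin_label,), None,
        )
        three = _PlannedGene(
            "toxin", element_id, el.strand,
            _labelled_protein(rng, el.toxin_label, n_aa(SENTINEL_LENGTH + 2)),
            (el.toxin_label,), el.gap_nt,
        )
        genes = [five, three]  # 5'->3'
        if el.strand == "-":
            genes = _reverse_run(genes)
        return genes
    if isinstance(el, OperonSpec):
        genes = []
        for i, lab in enumerate(el.labels):
            genes.append(
                _PlannedGene(
                    "operon-member", element_id, el.strand,
                    _labelled_protein(rng, lab, n_aa(SENTINEL_LENGTH + 2)),
                    (lab,), None if i == 0 else el.gaps_nt[i - 1],
                )
            )
        if el.strand == "-":
            genes = _reverse_run(genes)
        return genes
    if isinstance(el, DivergonSpec):
        left = _PlannedGene(
            "divergon-left", element_id, "-",
            _labelled_protein(rng, el.labels[0], n_aa(SENTINEL_LENGTH + 2)),
            (el.labels[0],), None,
        )
        right = _PlannedGene(
            "divergon-right", element_id, "+",
            _labelled_protein(rng, el.labels[1], n_aa(SENTINEL_LENGTH + 2)),
            (el.labels[1],), el.head_gap_nt,
        )
        return [left, right]
    if isinstance(el, FusionSpec):
        need = SENTINEL_LENGTH * len(el.domain_labels) + len(el.domain_labels) + 1
        return [
            _PlannedGene(
                "fusion", element_id, "+",
                _fusion_protein_seq(rng, el.domain_labels, n_aa(need)),
                tuple(el.domain_labels), None,
            )
        ]
    raise TypeError(f"unknown planted element {el!r}")


def _reverse_run(genes: list[_PlannedGene]) -> list[_PlannedGene]:
    """Convert a 5'->3' gene list on '-' to genomic (left-to-right) order."""
    rev = list(reversed(genes))
    gaps = [g.gap_before for g in genes[1:]][::-1]
    out = []
    for i, g in enumerate(rev):
        out.append(
            _PlannedGene(
                g.role, g.element_id, g.strand, g.protein, g.domains,
                None if i == 0 else gaps[i - 1],
            )
        )
    return out


def generate_genome(plan: GenomePlan) -> tuple[ContigRecord, TruthTable]:
    """Generate one synthetic contig and its truth table.

    Planted elements appear with exactly the requested intra-element
    gaps and strands, separated from neighbours by large (>300 nt) gaps;
    background genes fill the rest with mixture-drawn gaps.  Raises on
    infeasible plans (gaps out of range, genes too short for their
    sentinels, or overlaps that would reorder gene starts).
    """
    rng = np.random.default_rng(plan.seed)
    aa_range = (plan.gene_length_range[0] // 3 - 1, plan.gene_length_range[1] // 3 - 1)
    if aa_range[0] < SENTINEL_LENGTH + 2:
        aa_range = (SENTINEL_LENGTH + 2, max(aa_range[1], SENTINEL_LENGTH + 3))

    units: list[list[_PlannedGene]] = []
    for i, el in enumerate(plan.planted_elements):
        eid = f"{el.kind}{i + 1:02d}"
        units.append(_element_genes(el, eid, rng, aa_range))
    for j in range(plan.n_background_genes):
        units.append(
            [
                _PlannedGene(
                    "background", "", plan.background_strand,
                    _random_protein(rng, int(rng.integers(*aa_range))),
                    (), None,
                )
            ]
        )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    genes: list[GeneRecord] = []
    truth_genes: dict[str, TruthRecord] = {}
    elements: dict[str, list[str]] = {}
    element_kind: dict[str, str] = {}
    pos = int(rng.integers(50, 200))
    counter = 0
    prev_planted = False
    for unit in units:
        planted = bool(unit[0].element_id)
        first = True
        for pg in unit:
            counter += 1
            gid = f"g{counter:04d}"
            if not first:
                gap = pg.gap_before
                if gap is None:
                    raise ValueError("internal: missing intra-element gap")
            elif genes:
                if planted or prev_planted:
                    gap = int(rng.integers(*plan.large_gap_range))
                elif rng.random() < plan.small_gap_weight:
                    gap = int(rng.integers(plan.small_gap_range[0],
                                           plan.small_gap_range[1] + 1))
                else:
                    gap = int(rng.integers(*plan.large_gap_range))
            else:
                gap = 0
            start = pos + gap if genes else pos
            nt_len = 3 * (len(pg.protein) + 1)
            if genes and start <= genes[-1].start:
                raise ValueError(
                    "infeasible plan: overlap would reorder gene starts "
                    f"(gap {gap} before {gid})"
                )
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    contig_id=plan.contig_id,
                    start=start,
                    end=start + nt_len,
                    strand=pg.strand,
                    product=pg.role or "hypothetical protein",
                    protein_seq=pg.protein,
                )
            )
            truth_genes[gid] = TruthRecord(
                gene_id=gid,
                element_id=pg.element_id,
                role=pg.role,
                domains=pg.domains,
            )
            if pg.element_id:
                elements.setdefault(pg.element_id, []).append(gid)
                element_kind[pg.element_id] = pg.element_id.rstrip("0123456789")
            pos = start + nt_len
            first = False
        prev_planted = planted

    length = pos + int(rng.integers(50, 200))
    contig = ContigRecord(
        contig_id=plan.contig_id, length=length, genes=genes,
        circular=plan.circular,
    )
    # element gene lists: store dyad/operon members 5'->3'
    elements_final: dict[str, tuple[str, tuple[str, ...]]] = {}
    for eid, gids in elements.items():
        kind = element_kind[eid]
        ordered = tuple(gids)
        if kind in {"ta_dyad", "operon"}:
            strand = contig.gene(gids[0]).strand
            if strand == "-":
                ordered = tuple(reversed(gids))
        elements_final[eid] = (kind, ordered)
    return contig, TruthTable(genes=truth_genes, elements=elements_final)


def contig_nucleotide_sequence(contig: ContigRecord, seed: int = 0) -> str:
    """Back-translated nucleotide sequence consistent with the contig's genes.

    Coding spans are filled codon-by-codon (one fixed codon per residue
    plus a TAA stop, reverse-complemented on '-'); intergenic spans with
    seeded random nucleotides.  Overlapping genes are filled in gene
    order, later genes overwriting the overlap (sequence content is a
    carrier; analysis runs on coordinates and translations).
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=contig.length)))
    for g in contig.genes:
        cds = "".join(_CODON.get(aa, "NNN") for aa in g.protein_seq) + "TAA"
        cds = cds[: g.end - g.start].ljust(g.end - g.start, "A")
        if g.strand == "-":
            cds = cds.translate(_COMP)[::-1]
        seq[g.start : g.end] = cds
    return "".join(seq)


def write_dataset(
    contig: ContigRecord, truth: TruthTable, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Emit the GenBank file, protein FASTA and truth TSV for a contig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": out / f"{contig.contig_id}.gbk",
        "fasta": out / f"{contig.contig_id}.faa",
        "truth": out / f"{contig.contig_id}.truth.tsv",
    }
    write_genbank(contig, paths["genbank"],
                  sequence=contig_nucleotide_sequence(contig, seed))
    write_fasta({g.gene_id: g.protein_seq for g in contig.genes}, paths["fasta"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\telement_id\trole\tdomains\n")
        for gid in sorted(truth.genes):
            t = truth.genes[gid]
            fh.write(f"{gid}\t{t.element_id}\t{t.role}\t{','.join(t.domains)}\n")
    return paths


# ---------------------------------------------------------------------------
# motif and family fixtures

@dataclass(frozen=True)
class MotifTruth:
    r_pos: int
    spacer: int
    h_pos: int
    polar_after_r: bool
    upstream_exkr_pos: int | None


def plant_motif(
    length: int,
    spacer: int = 4,
    polar_after_r: bool = True,
    with_upstream_exkr: bool = False,
    seed: int = 0,
) -> tuple[str, MotifTruth]:
    """A protein sequence containing exactly one R-x{spacer}-H site.

    The background alphabet contains no R, H, E or K, so no second
    R-x{4..6}-H site and no stray Ex3[KR] can arise; the planted site's
    coordinates are returned as truth.
    """
    if not 4 <= spacer <= 6:
        raise ValueError("spacer must be in [4, 6]")
    if length < spacer + 10:
        raise ValueError(f"length {length} too small for spacer {spacer}")
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(MOTIF_BACKGROUND), size=length)))
    lo = 5 if with_upstream_exkr else 0
    hi = length - spacer - 2
    r_pos = int(rng.integers(lo, hi + 1))
    h_pos = r_pos + spacer + 1
    seq[r_pos] = "R"
    seq[h_pos] = "H"
    if polar_after_r:
        seq[r_pos + 1] = str(rng.choice(["N", "D"]))
    else:
        seq[r_pos + 1] = str(rng.choice(list("ACFGILMPVWY")))
    exkr_pos = None
    if with_upstream_exkr:
        exkr_pos = int(rng.integers(0, r_pos - 4))
        seq[exkr_pos] = "E"
        seq[exkr_pos + 4] = "K"
    return "".join(seq), MotifTruth(
        r_pos=r_pos,
        spacer=spacer,
        h_pos=h_pos,
        polar_after_r=polar_after_r,
        upstream_exkr_pos=exkr_pos,
    )


def generate_protein_family(
    n_seqs: int, conservation_profile: Sequence, seed: int = 0
) -> Alignment:
    """Sample an ungapped family alignment from a per-column profile.

    Column specs: a single residue letter (invariant column), a class
    code 'h'/'p'/'s' (drawn uniformly from the class), 'random' (any of
    the 20 residues) or a (residue, fraction) pair — the residue with
    the given probability, otherwise a uniformly chosen other residue.
    """
    if n_seqs < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    cols = []
    for spec in conservation_profile:
        if isinstance(spec, tuple):
            res, frac = spec
            others = [a for a in AA20 if a != res]
            hit = rng.random(n_seqs) < frac
            draw = rng.choice(others, size=n_seqs)
            cols.append([res if h else d for h, d in zip(hit, draw)])
        elif spec == "random":
            cols.append(list(rng.choice(list(AA20), size=n_seqs)))
        elif spec in RESIDUE_CLASSES:
            members = sorted(RESIDUE_CLASSES[spec])
            cols.append(list(rng.choice(members, size=n_seqs)))
        elif isinstance(spec, str) and len(spec) == 1 and spec in AA20:
            cols.append([spec] * n_seqs)
        else:
            raise ValueError(f"unknown column spec {spec!r}")
    rows = ["".join(col[i] for col in cols) for i in range(n_seqs)]
    return Alignment(names=[f"seq{i + 1}" for i in range(n_seqs)], rows=rows)
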