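"""Reading and writing annotated genomes, alignments and result tables.

Internal coordinates are 0-based half-open throughout, so ``end - start``
is the nucleotide span and intergenic distances need no off-by-one
corrections.  GenBank's 1-based inclusive convention is converted at the
I/O boundary only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import BiopythonParserWarning, SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: ambiguous one-letter codes mapped to X on ingest
AMBIGUOUS_AA = set("BZJUO*")


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene (CDS) on a contig.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the contig; ``strand`` is '+' or '-'.  ``protein_seq``
    may be empty for pseudogenes or CDS features without a translation.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        bad = set(self.protein_seq) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-standard residues {sorted(bad)}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Position of the 5' end of the gene (transcription start side)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ContigRecord:
    """A contig with its genes sorted by start coordinate."""

    contig_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds contig length {self.length}"
                )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene ids on contig {self.contig_id}")

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r} on contig {self.contig_id}")


@dataclass
class Alignment:
    """A gapped multiple alignment of amino-acid sequences ('-' gaps)."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(
                f"ragged alignment rows, lengths {sorted(len(r) for r in self.rows)}"
            )
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        if not 0 <= i < self.width:
            raise IndexError(f"column {i} out of range for width {self.width}")
        return "".join(row[i] for row in self.rows)


def _sanitize_protein(seq: str, gene_id: str) -> str:
    out = []
    warned = False
    for aa in seq.upper():
        if aa in STANDARD_AA or aa == "X":
            out.append(aa)
        else:
            if not warned:
                logger.warning(
                    "gene %s: ambiguous residue(s) mapped to X", gene_id
                )
                warned = True
            out.append("X")
    return "".join(out)


def read_genbank(path: str | Path) -> list[ContigRecord]:
    """Parse a GenBank flat file into :class:`ContigRecord` objects.

    Every CDS feature becomes a :class:`GeneRecord`; 1-based inclusive
    GenBank locations become 0-based half-open, compound (join) locations
    collapse to their outer span, and complement-strand features get
    strand '-'.  CDS features without a /translation are retained with an
    empty protein sequence and a logged warning.  Non-CDS features are
    ignored.
    """
    path = Path(path)
    contigs: list[ContigRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonParserWarning)
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except ValueError as exc:
            raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    for rec in records:
        genes = []
        n_cds = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            if feat.location is None:
                raise ValueError(
                    f"malformed record {rec.id}: CDS feature without location"
                )
            start = int(feat.location.start)  # Biopython is already 0-based
            end = int(feat.location.end)  # outer span for compound locations
            strand = "-" if feat.location.strand == -1 else "+"
            gene_id = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("protein_id", [None])[0]
                or f"{rec.id}_cds{n_cds}"
            )
            translation = feat.qualifiers.get("translation", [""])[0]
            if not translation:
                logger.warning("gene %s: CDS without translation", gene_id)
            product = feat.qualifiers.get("product", [""])[0]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    protein_seq=_sanitize_protein(translation, gene_id),
                )
            )
        topology = rec.annotations.get("topology", "linear")
        contigs.append(
            ContigRecord(
                contig_id=rec.id,
                length=len(rec.seq),
                genes=genes,
                circular=(topology == "circular"),
            )
        )
    all_ids = [g.gene_id for c in contigs for g in c.genes]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError(f"duplicate gene ids across contigs in {path}")
    return contigs


def write_genbank(
    contig: ContigRecord, path: str | Path, sequence: str | None = None
) -> None:
    """Emit a contig as a GenBank flat file.

    ``sequence`` is the contig nucleotide sequence; if omitted an all-N
    placeholder of the right length is written (coordinates, strands and
    translations are what downstream analysis consumes).
    """
    seq = Seq(sequence if sequence is not None else "N" * contig.length)
    if len(seq) != contig.length:
        raise ValueError("sequence length does not match contig length")
    rec = SeqRecord(
        seq,
        id=contig.contig_id,
        name=contig.contig_id[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if contig.circular else "linear",
        },
    )
    for g in contig.genes:
        feat = SeqFeature(
            FeatureLocation(g.start, g.end, strand=-1 if g.strand == "-" else 1),
            type="CDS",
            qualifiers={
                "locus_tag": [g.gene_id],
                "product": [g.product] if g.product else ["hypothetical protein"],
            },
        )
        if g.protein_seq:
            feat.qualifiers["translation"] = [g.protein_seq]
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; rows must have equal length."""
    path = Path(path)
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ValueError(f"no sequences in alignment file {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(
            f"ragged alignment in {path}: row lengths {sorted(len(r) for r in rows)}"
        )
    return Alignment(names=names, rows=rows)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write protein sequences as FASTA, in input order."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_table(records: Iterable, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses or mappings) as a TSV with a header.

    Column order follows ``columns`` or the first record's field order;
    rows are sorted by the first column so output is deterministic.  An
    empty record list writes a header-only file (``columns`` required
    then).
    """
    rows = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
        elif isinstance(rec, dict):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialise record of type {type(rec).__name__}")
    with open(path, "w") as fh:
        if not rows:
            fh.write(("\t".join(columns) if columns else "") + "\n")
            return
        cols = list(columns) if columns else list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in sorted(rows, key=lambda r: str(r[cols[0]])):
            fh.write("\t".join(_cell(row.get(c, "")) for c in cols) + "\n")


def _cell(value) -> str:
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def reverse_complement_contig(contig: ContigRecord) -> ContigRecord:
    """Flip a contig: reverse coordinates and swap strands.

    Used for orientation-invariance checks; gene content is unchanged.
    """
    L = contig.length
    genes = [
        replace(
            g,
            start=L - g.end,
            end=L - g.start,
            strand="-" if g.strand == "+" else "+",
        )
        for g in contig.genes
    ]
    return ContigRecord(
        contig_id=contig.contig_id,
        length=L,
        genes=genes,
        circular=contig.circular,
    )
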