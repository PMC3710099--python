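import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from hepnscape.genome_io import ContigRecord, GeneRecord


def make_contig(spec, contig_id="ctg", circular=False, start0=100, glen=200):
    """Build a contig from [(strand, gap_before), ...] compactly.

    ``gap_before`` is the intergenic distance to the previous gene and
    is ignored for the first gene.
    """
    genes = []
    pos = start0
    for i, (strand, gap) in enumerate(spec):
        if i > 0:
            pos += gap
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1}",
                contig_id=contig_id,
                start=pos,
                end=pos + glen,
                strand=strand,
                protein_seq="",
            )
        )
        pos += glen
    return ContigRecord(
        contig_id=contig_id, length=pos + 500, genes=genes, circular=circular
    )


@pytest.fixture
def simple_contig():
    return make_contig([("+", 0), ("+", 50), ("+", 120), ("-", 30), ("-", 10)])
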