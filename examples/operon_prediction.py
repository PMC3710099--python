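"""Predict operons and divergons on a hand-built contig using the
100-nt intergenic-distance criterion."""

from hepnscape.genome_io import ContigRecord, GeneRecord
from hepnscape.neighborhood import find_divergons, predict_operons

genes = [
    GeneRecord("mnt", "ctg", 100, 400, "+"),     # gap to next: 30 nt
    GeneRecord("hepn", "ctg", 430, 850, "+"),    # gap to next: 500 nt
    GeneRecord("solo", "ctg", 1350, 1700, "+"),  # isolated
    GeneRecord("left", "ctg", 2200, 2600, "-"),  # head-to-head with 'right'
    GeneRecord("right", "ctg", 2750, 3100, "+"),
]
contig = ContigRecord("ctg", 3600, genes)

for op in predict_operons(contig, max_gap=100):
    print(f"{op.operon_id}: strand {op.strand}  genes {'-'.join(op.gene_ids)}")
# mnt+hepn share an operon (30 nt <= 100); the 500-nt gap splits solo off.

for d in find_divergons(contig, max_head_gap=300):
    print(f"divergon: {d.left_gene_id} <-> {d.right_gene_id}, head gap {d.head_gap} nt")
# only the (-,+) pair faces 5'-to-5' and may share a bidirectional promoter.
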