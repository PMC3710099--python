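"""The synthetic-genome generator and its truth tables."""

import pytest

from hepnscape.genome_io import read_genbank
from hepnscape.motif_engine import HYDROPHOBIC
from hepnscape.neighborhood import intergenic_distance
from hepnscape.synthetic_data import (
    GenomePlan,
    divergon,
    fusion_protein,
    generate_genome,
    generate_protein_family,
    operon,
    plant_motif,
    sentinel_sequence,
    ta_dyad,
    write_dataset,
)


def test_dyad_layout():
    """A planted dyad is two co-directional adjacent genes with the
    requested gap, antitoxin 5' of the toxin."""
    plan = GenomePlan(seed=2, n_background_genes=0,
                      planted_elements=[ta_dyad(gap_nt=30)])
    contig, truth = generate_genome(plan)
    assert len(contig.genes) == 2
    g1, g2 = contig.genes
    assert g1.strand == g2.strand == "+"
    assert intergenic_distance(g1, g2) == 30
    (eid, (kind, gids)), = truth.elements.items()
    assert kind == "ta_dyad" and gids == (g1.gene_id, g2.gene_id)
    assert truth.genes[gids[0]].role == "antitoxin"
    assert truth.genes[gids[1]].role == "toxin"
    assert sentinel_sequence("MNT") in g1.protein_seq
    assert sentinel_sequence("HEPN") in g2.protein_seq


def test_minus_strand_dyad_antitoxin_still_five_prime():
    plan = GenomePlan(seed=2, n_background_genes=0,
                      planted_elements=[ta_dyad(gap_nt=10, strand="-")])
    contig, truth = generate_genome(plan)
    left, right = contig.genes
    (kind, gids), = truth.elements.values()
    # 5'->3' on '-' runs right-to-left genomically
    assert gids == (right.gene_id, left.gene_id)
    assert truth.genes[right.gene_id].role == "antitoxin"


def test_background_only_plan():
    plan = GenomePlan(seed=3, n_background_genes=10, planted_elements=[])
    contig, truth = generate_genome(plan)
    assert len(contig.genes) == 10
    assert all(t.role == "background" for t in truth.genes.values())
    assert truth.elements == {}


def test_seed_determinism(tmp_path):
    plan = GenomePlan(seed=5, n_background_genes=8,
                      planted_elements=[ta_dyad(), fusion_protein()])
    p1 = write_dataset(*generate_genome(plan), tmp_path / "a", seed=plan.seed)
    p2 = write_dataset(*generate_genome(plan), tmp_path / "b", seed=plan.seed)
    assert p1["genbank"].read_bytes() == p2["genbank"].read_bytes()
    assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
    other = GenomePlan(seed=6, n_background_genes=8,
                       planted_elements=[ta_dyad(), fusion_protein()])
    p3 = write_dataset(*generate_genome(other), tmp_path / "c", seed=other.seed)
    assert p1["genbank"].read_bytes() != p3["genbank"].read_bytes()


def test_planted_gaps_and_negative_overlap():
    plan = GenomePlan(seed=8, n_background_genes=0,
                      planted_elements=[operon(["A", "B", "C"], [-20, 50])])
    contig, _ = generate_genome(plan)
    g = contig.genes
    assert intergenic_distance(g[0], g[1]) == -20
    assert intergenic_distance(g[1], g[2]) == 50


def test_infeasible_plans_raise():
    with pytest.raises(ValueError, match="outside"):
        GenomePlan(planted_elements=[ta_dyad(gap_nt=-60)])
    with pytest.raises(ValueError, match="outside"):
        GenomePlan(planted_elements=[operon(["A", "B"], [6000])])
    with pytest.raises(ValueError):
        GenomePlan(small_gap_range=(20, 150))  # small component must stay <=100


def test_background_separation_of_planted_elements():
    """Planted elements are flanked by gaps wider than both the operon
    and the divergon thresholds."""
    plan = GenomePlan(seed=9, n_background_genes=20,
                      planted_elements=[ta_dyad(), divergon(), fusion_protein()])
    contig, truth = generate_genome(plan)
    planted_ids = {gid for gid, t in truth.genes.items() if t.element_id}
    for a, b in zip(contig.genes, contig.genes[1:]):
        crossing = (a.gene_id in planted_ids) != (b.gene_id in planted_ids)
        same_element = (
            a.gene_id in planted_ids and b.gene_id in planted_ids
            and truth.genes[a.gene_id].element_id == truth.genes[b.gene_id].element_id
        )
        if crossing or (a.gene_id in planted_ids and not same_element):
            assert intergenic_distance(a, b) > 300


def test_plant_motif_contract():
    seq, truth = plant_motif(40, spacer=5, polar_after_r=True,
                             with_upstream_exkr=True, seed=4)
    assert seq[truth.r_pos] == "R" and seq[truth.h_pos] == "H"
    assert truth.h_pos == truth.r_pos + truth.spacer + 1
    assert seq[truth.upstream_exkr_pos] == "E"
    assert seq[truth.upstream_exkr_pos + 4] in "KR"
    with pytest.raises(ValueError, match="too small"):
        plant_motif(12, spacer=6)
    with pytest.raises(ValueError, match="spacer"):
        plant_motif(40, spacer=7)


def test_generate_protein_family_profiles():
    aln = generate_protein_family(30, ["R", "h", "random", ("R", 0.8)], seed=1)
    assert all(row[0] == "R" for row in aln.rows)
    assert all(row[1] in HYDROPHOBIC for row in aln.rows)
    with pytest.raises(ValueError, match="unknown column spec"):
        generate_protein_family(5, ["q"])
    aln = generate_protein_family(3, ["A", "A"])
    assert aln.rows == ["AA", "AA", "AA"]


def test_emitted_genbank_reparses(tmp_path):
    plan = GenomePlan(seed=12, n_background_genes=5,
                      planted_elements=[divergon(head_gap_nt=150)])
    contig, truth = generate_genome(plan)
    paths = write_dataset(contig, truth, tmp_path, seed=plan.seed)
    (back,) = read_genbank(paths["genbank"])
    assert [g.gene_id for g in back.genes] == [g.gene_id for g in contig.genes]
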