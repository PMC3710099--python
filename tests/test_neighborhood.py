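"""Operon partitioning, divergon detection and neighbourhood windows."""

import itertools

import pytest
from hypothesis import given, strategies as st

from conftest import make_contig
from oracles import brute_force_operons
from hepnscape.genome_io import GeneRecord
from hepnscape.neighborhood import (
    find_divergons,
    intergenic_distance,
    neighborhood,
    predict_operons,
)


def _gene(gid, start, end, strand="+"):
    return GeneRecord(gid, "ctg", start, end, strand)


@pytest.mark.parametrize(
    "iv1, iv2, expected",
    [((100, 200), (250, 350), 50), ((100, 200), (200, 300), 0), ((100, 200), (190, 290), -10)],
)
def test_intergenic_distance(iv1, iv2, expected):
    assert intergenic_distance(_gene("a", *iv1), _gene("b", *iv2)) == expected


def test_intergenic_distance_errors():
    a = _gene("a", 100, 200)
    b = GeneRecord("b", "other", 250, 350, "+")
    with pytest.raises(ValueError, match="different contigs"):
        intergenic_distance(a, b)


def test_predict_operons_examples():
    """Gaps of 50 and 120 around the 100-nt criterion split three
    co-directional genes into {g1,g2} and {g3}; alternating strands give
    all singletons."""
    c = make_contig([("+", 0), ("+", 50), ("+", 120)])
    ops = predict_operons(c)
    assert [op.gene_ids for op in ops] == [("g1", "g2"), ("g3",)]
    c = make_contig([("+", 0), ("-", 10), ("+", 10), ("-", 10)])
    assert all(len(op) == 1 for op in predict_operons(c))


def test_minus_strand_operon_order():
    """Within a '-' strand operon gene order is 5'->3', i.e. reversed
    genomic order."""
    c = make_contig([("-", 0), ("-", 20), ("-", 30)])
    (op,) = predict_operons(c)
    assert op.gene_ids == ("g3", "g2", "g1")
    assert op.span == (c.genes[0].start, c.genes[-1].end)


GAPS = [-10, 0, 50, 100, 101, 500]


def test_operon_oracle_small_exhaustive():
    """Exhaustive agreement with the brute-force segmentation for every
    strand assignment and gap combination on 2-4 gene contigs."""
    for n in (2, 3, 4):
        for strands in itertools.product("+-", repeat=n):
            for gaps in itertools.product(GAPS, repeat=n - 1):
                c = make_contig([(s, g) for s, g in zip(strands, (0,) + gaps)])
                got = [op.gene_ids for op in predict_operons(c)]
                assert got == brute_force_operons(c, 100), (strands, gaps)


@given(
    st.lists(
        st.tuples(st.sampled_from("+-"), st.sampled_from(GAPS)), min_size=1, max_size=8
    ),
    st.sampled_from([-100, 0, 100, 10**9]),
)
def test_operon_partition_properties(spec, max_gap):
    """The operon prediction is a partition: concatenating operons in
    genomic order reproduces the gene list; max_gap below all gaps gives
    singletons and above all gaps gives maximal same-strand runs."""
    c = make_contig(spec)
    ops = predict_operons(c, max_gap=max_gap)
    genomic = []
    for op in ops:
        members = list(op.gene_ids)
        if op.strand == "-":
            members.reverse()
        genomic.extend(members)
    assert genomic == [g.gene_id for g in c.genes]
    if max_gap == -100:
        assert all(len(op) == 1 for op in ops)
    if max_gap == 10**9:
        strands = [g.strand for g in c.genes]
        runs = len([1 for a, b in zip(strands, strands[1:]) if a != b]) + 1
        assert len(ops) == runs


@given(
    st.lists(
        st.tuples(st.sampled_from("+-"), st.sampled_from(GAPS)), min_size=1, max_size=8
    )
)
def test_operon_count_monotone_in_max_gap(spec):
    """Raising max_gap never increases the number of operons."""
    c = make_contig(spec)
    counts = [len(predict_operons(c, max_gap=mg)) for mg in (-100, 0, 50, 100, 500, 10**6)]
    assert counts == sorted(counts, reverse=True)


def test_find_divergons_strand_patterns():
    """Of the four adjacent strand patterns only (-,+) puts the 5' ends
    face to face."""
    for s1, s2 in itertools.product("+-", repeat=2):
        c = make_contig([(s1, 0), (s2, 100)])
        divs = find_divergons(c)
        if (s1, s2) == ("-", "+"):
            assert len(divs) == 1
            assert (divs[0].left_gene_id, divs[0].right_gene_id) == ("g1", "g2")
            assert divs[0].head_gap == 100
        else:
            assert divs == []


def test_find_divergons_gap_window():
    c = make_contig([("-", 0), ("+", 301)])
    assert find_divergons(c, max_head_gap=300) == []
    assert len(find_divergons(c, max_head_gap=301)) == 1
    # overlapping head-to-head genes are not a promoter-sharing pair
    c = make_contig([("-", 0), ("+", -10)])
    assert find_divergons(c) == []


def test_neighborhood_window():
    c = make_contig([("+", 0)] + [("+", 10)] * 4)
    mid = neighborhood(c, "g3", k=2)
    assert [g.gene_id for g in mid] == ["g1", "g2", "g3", "g4", "g5"]
    first = neighborhood(c, "g1", k=3)
    assert [g.gene_id for g in first] == ["g1", "g2", "g3", "g4"]
    with pytest.raises(KeyError):
        neighborhood(c, "missing", k=1)


def test_neighborhood_circular_wrap():
    c = make_contig([("+", 0)] + [("+", 10)] * 4, circular=True)
    got = [g.gene_id for g in neighborhood(c, "g1", k=1)]
    assert got == ["g5", "g1", "g2"]
    # window larger than the contig returns every gene exactly once
    got = [g.gene_id for g in neighborhood(c, "g1", k=10)]
    assert sorted(got) == ["g1", "g2", "g3", "g4", "g5"]
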