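"""Rx4-6H motif scanning, conservation and active-site classification."""

import random

import pytest

from oracles import oracle_consensus_char, oracle_rxh_sites
from hepnscape.genome_io import Alignment
from hepnscape.motif_engine import (
    classify_active_site,
    column_conservation,
    consensus_line,
    scan_rxh,
)
from hepnscape.synthetic_data import generate_protein_family, plant_motif


def test_scan_rxh_examples():
    hits = scan_rxh("AAARNPQGHAA")
    assert len(hits) == 1
    h = hits[0]
    assert (h.r_pos, h.spacer, h.h_pos) == (3, 4, 8)
    assert h.polar_after_r and h.polar_preferred  # N follows the R
    assert scan_rxh("AAARNPQGKAA") == []  # no histidine
    with pytest.raises(ValueError, match="gapped"):
        scan_rxh("AAR--NPQH")


def test_scan_rxh_overlapping_hits_and_exkr():
    # one R pairing with two downstream histidines at spacers 4 and 6
    hits = scan_rxh("RAAAAHAHAA")
    assert [(h.spacer, h.h_pos) for h in hits] == [(4, 5), (6, 7)]
    hits = scan_rxh("EAAAKARNPQGHAA")
    assert hits[0].upstream_exkr_pos == 0


def test_scan_rxh_against_enumeration_oracle():
    """Hits equal an exhaustive position-pair enumeration on random
    sequences (R/H-enriched alphabet so sites actually occur)."""
    rng = random.Random(5)
    for trial in range(300):
        seq = "".join(rng.choice("RHANDEGLKST") for _ in range(rng.randint(1, 30)))
        got = [(h.r_pos, h.spacer, h.h_pos) for h in scan_rxh(seq)]
        assert got == oracle_rxh_sites(seq), seq


@pytest.mark.parametrize("spacer", [4, 5, 6])
@pytest.mark.parametrize("exkr", [False, True])
def test_plant_motif_closure(spacer, exkr):
    """Scanning a planted-motif sequence returns exactly the planted
    site with the planted evidence flags."""
    for seed in range(50):
        seq, truth = plant_motif(
            60, spacer=spacer, polar_after_r=(seed % 2 == 0),
            with_upstream_exkr=exkr, seed=seed,
        )
        hits = scan_rxh(seq)
        assert len(hits) == 1
        h = hits[0]
        assert (h.r_pos, h.spacer, h.h_pos) == (truth.r_pos, truth.spacer, truth.h_pos)
        assert h.polar_after_r == truth.polar_after_r
        assert h.upstream_exkr_pos == truth.upstream_exkr_pos


def test_column_conservation():
    aln = Alignment(names=list("ab"), rows=["RH", "RD"])
    assert column_conservation(aln, 0) == ("R", 1.0)
    # 1x H vs 1x D: lexicographic tie rule picks D
    assert column_conservation(aln, 1) == ("D", 0.5)
    aln = Alignment(names=["a"], rows=["-"])
    assert column_conservation(aln, 0) == ("-", 0.0)


def test_consensus_line_classes():
    """Class columns collapse to their Figure-legend codes: LIVF is
    hydrophobic (h), EDKN polar (p), AGSP small (s); a class-spanning
    mixture gives '.'."""
    aln = Alignment(
        names=list("abcd"),
        rows=["LEAW", "IDGE", "VKSG", "FNPA"],
    )
    assert consensus_line(aln) == "hps."


def test_consensus_agrees_with_conservation():
    """Wherever the consensus emits an uppercase residue its column
    conservation reaches the threshold, and every character matches the
    direct set-membership oracle."""
    rng = random.Random(9)
    for trial in range(30):
        n, w = rng.randint(1, 8), rng.randint(1, 12)
        rows = [
            "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY-") for _ in range(w))
            for _ in range(n)
        ]
        aln = Alignment(names=[f"s{i}" for i in range(n)], rows=rows)
        line = consensus_line(aln, threshold=0.7)
        for i, ch in enumerate(line):
            assert ch == oracle_consensus_char(aln.column(i), 0.7)
            if ch.isupper():
                top, frac = column_conservation(aln, i)
                assert top == ch and frac >= 0.7


def _family(profile, n=20, seed=0):
    return generate_protein_family(n, profile, seed=seed)


def test_classify_canonical():
    profile = list("AAA") + ["R", ("N", 0.9), "A", "A", "A", "A", "H"] + list("AA")
    aln = _family(profile)
    call = classify_active_site(aln)
    assert call.call == "active_canonical"
    assert call.evidence


def test_classify_alternative():
    """Conserved H N-terminal to a conserved basic column, with no
    canonical Rx4-6H site, is the displaced-histidine configuration."""
    profile = list("AA") + ["H"] + list("AAAA") + ["R"] + list("AAAAAA")
    aln = _family(profile)
    assert classify_active_site(aln).call == "active_alternative"


def test_classify_inactive():
    profile = ["h"] * 12
    aln = _family(profile)
    assert classify_active_site(aln).call == "inactive_binding"


def test_classify_row_order_and_gap_invariance():
    profile = list("AAA") + ["R", "N", "A", "A", "A", "A", "H"] + list("AA")
    aln = _family(profile, n=10)
    ref = classify_active_site(aln)
    reordered = Alignment(names=list(reversed(aln.names)),
                          rows=list(reversed(aln.rows)))
    assert classify_active_site(reordered).call == ref.call
    padded = Alignment(names=aln.names + ["gap"], rows=aln.rows + ["-" * aln.width])
    assert classify_active_site(padded).call == ref.call


def test_classify_single_sequence_and_errors():
    assert classify_active_site("AAARNPQGHAA").call == "active_canonical"
    assert classify_active_site("AAHAAAAKAAA").call == "active_alternative"
    assert classify_active_site("LLLVVVAAAWWW").call == "inactive_binding"
    with pytest.raises(ValueError):
        classify_active_site("")
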