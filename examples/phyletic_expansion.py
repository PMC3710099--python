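"""Tally a family-by-taxon copy-number matrix and flag lineage-specific
expansions (LSEs)."""

from hepnscape.phyletics import build_matrix, detect_lse

# gene -> (family, taxon): one crustacean-like genome with a massive
# expansion of one family against a 1-2 copy background elsewhere
assignments = {}
for i in range(46):
    assignments[f"dap_{i}"] = ("HEPN-like", "crustacean")
for taxon, copies in [("insect", 2), ("nematode", 1), ("chordate", 1)]:
    for i in range(copies):
        assignments[f"{taxon}_{i}"] = ("HEPN-like", taxon)
assignments["x1"] = ("MNT", "insect")

matrix = build_matrix(assignments)
print(matrix)

for call in detect_lse(matrix, min_copies=10, min_fold=5):
    print(
        f"LSE: {call.family} in {call.taxon}: {call.copy_count} copies "
        f"vs background median {call.background_median}"
    )
# 46 copies >= 10 and >= 5x the median over other taxa: the hallmark of a
# lineage-specific proliferation typical of conflict-related gene families.
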