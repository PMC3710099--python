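"""Cluster neighbouring proteins by global-alignment identity and label
each cluster with its plurality domain architecture."""

from hepnscape.homology_cluster import (
    annotate_clusters,
    cluster_proteins,
    pairwise_identity,
)

seqs = {
    "p1": "MKLVWFYPQSTNDEAGILMK",
    "p2": "MKLVWFYPQSTNDEAGILMR",   # 1 substitution vs p1
    "p3": "MKLVWFYPQSANDEAGILMR",   # 1 substitution vs p2
    "p4": "WWWWGGGGCCCCWWWWGGGG",   # unrelated
}
ps = pairwise_identity(seqs["p1"], seqs["p2"], "p1", "p2")
print(f"p1 vs p2: identity {ps.identity:.2f}, coverage {ps.coverage:.2f}")

clusters = cluster_proteins(seqs, identity_threshold=0.9, coverage_threshold=0.7)
for c in clusters.clusters:
    print("cluster:", "+".join(c))
# p1~p2 and p2~p3 each pass 90% identity, so single linkage chains all
# three into one cluster even if p1~p3 alone would fall short.

labels = annotate_clusters(clusters, {"p1": "HEPN", "p2": "HEPN", "p3": "MNT+HEPN"})
for members, (label, frac) in labels.items():
    print(f"{'+'.join(members)}: label {label} (plurality {frac:.2f})")
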