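"""Scan for the Rx4-6H RNase active-site motif and classify a family
alignment as catalytically active or inactive."""

from hepnscape.motif_engine import classify_active_site, consensus_line, scan_rxh
from hepnscape.synthetic_data import generate_protein_family, plant_motif

seq, truth = plant_motif(60, spacer=4, polar_after_r=True,
                         with_upstream_exkr=True, seed=7)
(hit,) = scan_rxh(seq)
print(f"site: R at {hit.r_pos}, spacer {hit.spacer}, H at {hit.h_pos}")
print(f"polar residue after R: {hit.polar_after_r}  "
      f"upstream Ex3[KR] at: {hit.upstream_exkr_pos}")
# the arginine and histidine of Rx4-6H form the predicted catalytic pair;
# the polar follower and the upstream acidic element are supporting evidence.

# a family with an invariant R and H six columns apart (spacer 5)
profile = ["h", "h", "R", ("N", 0.9), "random", "s", "s", "p", "H", "h"]
family = generate_protein_family(50, profile, seed=1)
print("consensus:", consensus_line(family, threshold=0.7))
call = classify_active_site(family)
print(f"classification: {call.call}  ({'; '.join(call.evidence)})")
# active_canonical: both motif columns are conserved in >=80% of rows.
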