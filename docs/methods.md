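# Methods

## The analysis model

The package operationalises a contextual-inference workflow for
HEPN-like defense systems: genes are intervals with strands on contigs
(0-based half-open internally; GenBank's 1-based inclusive convention is
converted at the I/O boundary, and compound `join` locations collapse to
their outer span, since introns are irrelevant to prokaryotic
neighbourhood analysis).

### Operons and divergons

An operon is a maximal run of co-directional genes in which every
consecutive intergenic distance (`next.start − prev.end`) is at most
`max_gap` (default **100 nt**). "Sharing a promoter" is deliberately
reduced to this distance + co-directionality proxy — no promoter
sequence model is applied, and the criterion is applied to CDS
boundaries as annotated. Overlapping genes (negative distance, permitted
to −50 nt by the generator) always merge: overlap is stronger evidence
of co-transcription than a small gap. On circular contigs a run may wrap
the origin when `circular` is set; it is reported once, anchored at its
5′-most gene. Gene order inside an operon is transcriptional (5′→3′),
i.e. reversed genomic order on the − strand.

A divergon is an adjacent (−,+) gene pair whose 5′ ends face each other
across a non-negative gap of at most `max_head_gap` (default **300 nt**
— no value is fixed by convention, this covers typical bidirectional
promoter spans and is configurable). Overlapping head-to-head pairs are
not reported: two overlapping 5′ ends cannot flank a shared promoter.

### Pairwise identity and clustering

The neighbour-clustering step replaces a BLASTCLUST-style tool with a
fixed, bit-reproducible scheme: global (Needleman–Wunsch/Gotoh)
alignment with match +1, mismatch −1, gap open −5, gap extend −1
(a length-L gap costs 5 + (L−1)); `X` matches nothing, including
another `X`. Identity is identical columns over alignment columns
excluding terminal gaps; coverage is residue-to-residue aligned columns
over the shorter sequence's length. Because co-optimal alignments can
disagree on these statistics, the score is made canonical: among all
maximum-score alignments, the one maximising (identical columns, then
residue-paired columns, then terminal-gap columns) lexicographically
defines the reported values. The DP packs the four additive components
into one integer per cell, so the canonical optimum falls out of a
plain `max` with no traceback. Clustering is single linkage (union-find
over pairs passing both thresholds); defaults are **30% identity / 70%
coverage**, a documented choice since no canonical thresholds exist for
this step. A length-ratio prefilter was considered and rejected: with
coverage defined against the shorter sequence, a short sequence fully
aligned inside a long one has coverage 1.0, so no length ratio bounds
coverage and any such filter would be lossy.

### Motif scanning and activity classification

`scan_rxh` reports every R-x{4..6}-H site (overlaps included; spacer 5
is accepted as part of the printed 4–6 range even though 4 and 6 are the
discussed variants). Two evidence features ride along: whether the
residue immediately after the R is polar, preferring {N, D, H} over the
broad polar class, and the position of an upstream Ex3[KR] element.
Both are evidence, never requirements, for an active call.

Family-level classification (threshold **0.8** column conservation by
default; family conservation in the 80–95% range motivates the cutoff,
which is configurable):

* `active_canonical` — some Rx4-6H site maps to the same (R, H) column
  pair in ≥ threshold of rows, and both columns are conserved;
* `active_alternative` — no such site, but a conserved H column lies
  N-terminal to a conserved basic (K/R) column — the displaced-histidine
  configuration seen in families where the canonical H is lost;
* `inactive_binding` — no conserved charged/polar catalytic columns, the
  presumed RNA-binding-only state.

Consensus lines use the residue classes h = WFYMLIVACTH,
p = EDKRNQHTS, s = ACDGNPSTV. The classes overlap (H, T, and others are
in two classes); precedence h > p > s is fixed for determinism. A column
prints its residue letter when a single residue reaches the threshold
(default 0.7), else the first qualifying class code, else `.`.

### Architectures and the context network

Domain detectors are exact sentinels (the synthetic genomes' realisation
of domains), PWMs scored as summed per-position log-odds over a sliding
window, and residue regexes. Overlap resolution is greedy
best-score-first (ties: earliest start, then name); losers are dropped,
not trimmed, and the result is independent of library order.

The context network has domain nodes and two edge types: *fusion* edges
between adjacent domains of one polypeptide (A+B+C yields (A,B) and
(B,C), never (A,C)) and *neighbourhood* edges between domains carried by
**different** genes of one operon — domains of the same protein never
get a neighbourhood edge, which resolves the ambiguity of drawing both
edge kinds from one gene. Weights count supporting instances (distinct
proteins / distinct operons); a pair repeated inside one instance counts
once. Edges are stored undirected with lexicographic endpoint order —
renderings of such graphs are undirected layouts — and the N→C
orientation of the first supporting fusion is kept as an attribute.
Category collapse merges parallel edges by summed weight (conserving
total weight exactly) and turns intra-category edges into self-loops.
Layout is Kamada–Kawai per connected component (deterministic;
components placed on a 4-unit grid, singletons at their cell origin,
scale chosen so a two-node edge comes out near unit length).

### TA dyads and context categories

A dyad call requires exactly a two-gene operon with one gene carrying a
toxin-set domain (default {HEPN}) and the other an antitoxin-set domain
(default {MNT}). Orientation is `canonical` iff the antitoxin is 5′ *in
the operon's strand frame*, making the call invariant to
reverse-complementing the contig. The antitoxin-5′ preference is
reported as an orientation fraction, not asserted as a threshold, since
"almost always" is not a number. Larger defense operons are classified
by majority vote of member domains against a curated domain→category
map (R-M, CRISPR-Cas, Abi, Pgl, TerD, TA) that ships as editable
configuration — it is curation, not computation; ties break
lexicographically and are flagged.

### Phyletics and LSEs

The phyletic matrix is a pure tally of (family, taxon) gene assignments
(taxon = genome/assembly id; higher ranks via a user lineage map). An
LSE is flagged when a cell has ≥ `min_copies` (default **10**) and
≥ `min_fold` (default **5×**) the median copy number over the *other*
taxa, a zero median counting as satisfied. The defaults are documented
choices motivated by the observed contrast between a 46-copy expansion
and the typical 1–2 copy background; no canonical cutoff exists.

## The synthetic world

The generator plants elements with exactly the requested intra-element
gaps and strands. Its fixed conventions:

* background intergenic gaps come from a two-component mixture,
  uniform 20–100 nt and uniform 400–1000 nt (weights 0.5/0.5), so the
  100-nt rule is exercised non-trivially on background genes too;
* every planted element is flanked by large-component gaps (400–1000
  nt), beyond both the operon and the divergon thresholds, so planted
  boundaries are unambiguous in the noise-free setting;
* background genes sit on the + strand by default (configurable), so
  the only head-to-head arrangements are planted divergons;
* domains are 30-residue sentinels drawn deterministically from the
  domain name over an R/H-free alphabet, so planted domains can never
  mimic the catalytic motif; gene lengths default to 300–900 nt;
* `plant_motif` backgrounds exclude R, H, E and K, so exactly one
  R-x{4..6}-H site and at most one Ex3[KR] exist, at recorded
  coordinates.

What a green recovery test establishes: the distance/strand/domain
rules re-derive planted structure exactly in a noise-free genome. What
it does not establish: robustness to annotation errors, missed or
fragmented CDS calls, sequence divergence of real domains (sentinels
are exact), compositional biases, or database-scale family censuses —
real-data domain calls should come from an external HMM tool via the
TSV import path. Recovery metrics score dyads, divergons and fusions
against all predictions (the background cannot produce them), but
operons only against predictions touching planted operon genes, because
background genes legitimately form unlabelled operons under the mixture
gap rule.

## Numerical and degenerate-input conventions

Ties everywhere break lexicographically (column consensus top residue,
cluster labels, context categories, edge endpoint order); ids are
assigned in genomic order. Gap-only alignment columns conserve nothing
and print `.`; empty architectures stringify as `unknown`; an empty
record list still writes a TSV header when columns are supplied.
Ambiguous amino acids other than X map to X with a warning on ingest.
LSE detection refuses single-taxon matrices (no background exists).
Seeds fully determine every generator output, and identical plans +
seeds produce byte-identical GenBank files.
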