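"""Single-linkage homology clustering of neighbouring proteins.

Replaces the external BLASTCLUST step with a self-contained, bit-
reproducible equivalent: global pairwise alignment with a fixed scoring
scheme (match +1, mismatch -1, gap open -5, gap extend -1; X matches
nothing), thresholds on percent identity and coverage, and single-
linkage (connected-component) clustering of the thresholded pair graph.

Because co-optimal alignments can differ in identity, the pair score is
made canonical: among all maximum-score global alignments the one
maximising, lexicographically, (identical columns, residue-to-residue
columns, terminal-gap columns) defines identity and coverage.  This is
computed exactly by a Gotoh-style dynamic programme over lexicographic
tuples packed into integers — no traceback or enumeration needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

MATCH = 1
MISMATCH = -1
GAP_OPEN = -5  # cost of the first residue of a gap
GAP_EXTEND = -1  # each further residue

DEFAULT_IDENTITY = 0.3
DEFAULT_COVERAGE = 0.7

_NEG = float("-inf")


@dataclass(frozen=True)
class PairScore:
    """Identity/coverage of the canonical optimal global alignment of a pair."""

    id_a: str
    id_b: str
    identity: float  # identical columns / columns excluding terminal gaps
    coverage: float  # residue-to-residue aligned columns / shorter length

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


@dataclass
class ClusterSet:
    """Disjoint clusters of sequence ids plus the thresholds that made them."""

    clusters: list[tuple[str, ...]]
    identity_threshold: float
    coverage_threshold: float

    def cluster_of(self, seq_id: str) -> tuple[str, ...]:
        for c in self.clusters:
            if seq_id in c:
                return c
        raise KeyError(seq_id)


def _align_stats(a: str, b: str) -> tuple[int, int, int, int]:
    """Canonical optimal global alignment statistics for two sequences.

    Returns ``(score, matches, paired_cols, terminal_gap_cols)`` of the
    alignment maximising (score, matches, paired_cols, terminal_gap_cols)
    lexicographically.  A gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND;
    terminal gaps are scored like internal ones.  The four quantities are
    packed into one integer per DP cell so the lexicographic maximum is a
    plain integer max.
    """
    n, m = len(a), len(b)
    # packing bases: matches, paired <= min(n,m); terminal gaps <= n+m
    KT = 1 << 14
    KC = 1 << 14
    KM = 1 << 14

    def pack(score: int, matches: int = 0, paired: int = 0, term: int = 0) -> int:
        return ((score * KM + matches) * KC + paired) * KT + term

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]  # a[i-1] aligned to b[j-1]
    IX = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    IY = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = pack(0)
    for i in range(1, n + 1):
        gap = GAP_OPEN + (i - 1) * GAP_EXTEND
        IX[i][0] = pack(gap, 0, 0, i)  # leading terminal gap columns
    for j in range(1, m + 1):
        gap = GAP_OPEN + (j - 1) * GAP_EXTEND
        IY[0][j] = pack(gap, 0, 0, j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        IXi, IXi1 = IX[i], IX[i - 1]
        IYi, IYi1 = IY[i], IY[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            ident = ai == bj and ai != "X"
            sub = MATCH if ident else MISMATCH
            best_prev = max(Mi1[j - 1], IXi1[j - 1], IYi1[j - 1])
            if best_prev != _NEG:
                Mi[j] = best_prev + pack(sub, 1 if ident else 0, 1, 0)
            # gap columns at the j == m boundary after b is exhausted are
            # trailing-terminal; likewise i == n for IY
            term_x = 1 if j == m else 0
            cand = []
            if Mi1[j] != _NEG:
                cand.append(Mi1[j] + pack(GAP_OPEN, 0, 0, term_x))
            if IXi1[j] != _NEG:
                cand.append(IXi1[j] + pack(GAP_EXTEND, 0, 0, term_x))
            if IYi1[j] != _NEG:
                cand.append(IYi1[j] + pack(GAP_OPEN, 0, 0, term_x))
            if cand:
                IXi[j] = max(cand)
            term_y = 1 if i == n else 0
            cand = []
            if Mi[j - 1] != _NEG:
                cand.append(Mi[j - 1] + pack(GAP_OPEN, 0, 0, term_y))
            if IYi[j - 1] != _NEG:
                cand.append(IYi[j - 1] + pack(GAP_EXTEND, 0, 0, term_y))
            if IXi[j - 1] != _NEG:
                cand.append(IXi[j - 1] + pack(GAP_OPEN, 0, 0, term_y))
            if cand:
                IYi[j] = max(cand)
    best = max(M[n][m], IX[n][m], IY[n][m])
    term = best % KT
    best //= KT
    paired = best % KC
    best //= KC
    matches = best % KM
    score = best // KM
    return int(score), int(matches), int(paired), int(term)


def pairwise_identity(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b") -> PairScore:
    """Score one pair of protein sequences.

    Identity is identical columns over alignment columns excluding
    terminal gaps; coverage is residue-to-residue aligned columns over
    the shorter sequence's length.  X is treated as matching nothing.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _, matches, paired, term = _align_stats(seq_a, seq_b)
    total_cols = len(seq_a) + len(seq_b) - paired
    core_cols = total_cols - term
    identity = matches / core_cols if core_cols else 0.0
    coverage = paired / min(len(seq_a), len(seq_b))
    return PairScore(id_a=id_a, id_b=id_b, identity=identity, coverage=coverage)


def cluster_proteins(
    seqs: Mapping[str, str],
    identity_threshold: float = DEFAULT_IDENTITY,
    coverage_threshold: float = DEFAULT_COVERAGE,
) -> ClusterSet:
    """Single-linkage clustering: connected components of the pair graph.

    Two sequences share a cluster iff they are connected by a chain of
    pairs each passing both the identity and the coverage threshold.
    Output clusters are sorted by their smallest member id, members
    sorted within each cluster, so the result is order-independent.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            ps = pairwise_identity(seqs[id_a], seqs[id_b], id_a, id_b)
            if ps.identity >= identity_threshold and ps.coverage >= coverage_threshold:
                ra, rb = find(id_a), find(id_b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = sorted((tuple(sorted(g)) for g in groups.values()), key=lambda c: c[0])
    return ClusterSet(
        clusters=clusters,
        identity_threshold=identity_threshold,
        coverage_threshold=coverage_threshold,
    )


def annotate_clusters(
    cluster_set: ClusterSet, architectures: Mapping[str, str]
) -> dict[tuple[str, ...], tuple[str, float]]:
    """Label each cluster with the plurality architecture of its members.

    ``architectures`` maps sequence id -> architecture string (missing
    members count as "unknown").  Ties break lexicographically; the
    returned fraction is the plurality share.  A cluster with no
    annotated member is labelled ("unknown", 0.0).
    """
    out = {}
    for cluster in cluster_set.clusters:
        counts: dict[str, int] = {}
        for member in cluster:
            arch = architectures.get(member, "unknown")
            counts[arch] = counts.get(arch, 0) + 1
        informative = {k: v for k, v in counts.items() if k != "unknown"}
        if not informative:
            out[cluster] = ("unknown", 0.0)
            continue
        label = min(informative, key=lambda k: (-informative[k], k))
        out[cluster] = (label, counts[label] / len(cluster))
    return out
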