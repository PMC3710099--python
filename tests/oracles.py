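"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a different route than the package
(direct rule evaluation, exhaustive enumeration, or a third-party
aligner) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

from Bio import Align
from Bio.Align import substitution_matrices

from hepnscape.genome_io import ContigRecord


# --------------------------------------------------------------------------
# operon segmentation by direct rule checking

def brute_force_operons(contig: ContigRecord, max_gap: int) -> list[tuple[str, ...]]:
    """All maximal co-directional runs with pairwise gaps <= max_gap,
    found by testing every candidate segmentation boundary directly.
    Returns gene-id tuples in 5'->3' order (linear contigs only)."""
    genes = contig.genes
    if not genes:
        return []
    # a boundary sits between i and i+1 iff the join rule fails there
    boundaries = [
        i
        for i in range(len(genes) - 1)
        if genes[i].strand != genes[i + 1].strand
        or (genes[i + 1].start - genes[i].end) > max_gap
    ]
    runs, start = [], 0
    for b in boundaries:
        runs.append(genes[start : b + 1])
        start = b + 1
    runs.append(genes[start:])
    out = []
    for run in runs:
        ordered = run if run[0].strand == "+" else list(reversed(run))
        out.append(tuple(g.gene_id for g in ordered))
    return out


# --------------------------------------------------------------------------
# canonical pairwise alignment statistics via Biopython enumeration

def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = 1.0 if (a == b and a != "X") else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _alignment_stats(row_a: str, row_b: str) -> tuple[int, int, int]:
    """(matches, paired_cols, terminal_gap_cols) of one gapped alignment."""
    matches = paired = 0
    cols = len(row_a)
    lead = 0
    while lead < cols and ("-" in (row_a[lead], row_b[lead])):
        lead += 1
    trail = 0
    while trail < cols - lead and ("-" in (row_a[cols - 1 - trail], row_b[cols - 1 - trail])):
        trail += 1
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            paired += 1
            if ca == cb and ca != "X":
                matches += 1
    return matches, paired, lead + trail


def oracle_pair_stats(a: str, b: str, cap: int = 50000) -> tuple[float, float]:
    """(identity, coverage) of the canonical optimal alignment, computed
    by enumerating Biopython's co-optimal global alignments and applying
    the (matches, paired, terminal) lexicographic selection rule."""
    alignments = _ALIGNER.align(a, b)
    best = None
    for i, aln in enumerate(alignments):
        if i >= cap:
            raise RuntimeError("too many co-optimal alignments to enumerate")
        row_a, row_b = str(aln[0]), str(aln[1])
        # terminal-gap columns: leading/trailing columns where either row gaps
        stats = _alignment_stats(row_a, row_b)
        if best is None or stats > best:
            best = stats
    matches, paired, term = best
    core = len(a) + len(b) - paired - term
    identity = matches / core if core else 0.0
    coverage = paired / min(len(a), len(b))
    return identity, coverage


def oracle_components(
    ids: list[str],
    passes: dict[tuple[str, str], bool],
) -> list[tuple[str, ...]]:
    """Connected components of the thresholded pair graph by plain BFS."""
    adj = {i: set() for i in ids}
    for (a, b), ok in passes.items():
        if ok:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for start in sorted(ids):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        comps.append(tuple(sorted(comp)))
    return sorted(comps, key=lambda c: c[0])


# --------------------------------------------------------------------------
# motif scanning by position enumeration (no regex, no shared code path)

def oracle_rxh_sites(seq: str, min_spacer: int = 4, max_spacer: int = 6):
    """All (r_pos, spacer, h_pos) with seq[r]=='R' and seq[h]=='H'."""
    sites = []
    for r, h in itertools.combinations(range(len(seq)), 2):
        spacer = h - r - 1
        if min_spacer <= spacer <= max_spacer and seq[r] == "R" and seq[h] == "H":
            sites.append((r, spacer, h))
    return sites


# --------------------------------------------------------------------------
# consensus by direct set-membership counting

def oracle_consensus_char(column: str, threshold: float) -> str:
    residues = [c for c in column if c != "-"]
    if not residues:
        return "."
    n = len(residues)
    counts = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    if top[1] / n >= threshold:
        return top[0]
    for code, members in (
        ("h", set("WFYMLIVACTH")),
        ("p", set("EDKRNQHTS")),
        ("s", set("ACDGNPSTV")),
    ):
        if sum(1 for c in residues if c in members) / n >= threshold:
            return code
    return "."


# --------------------------------------------------------------------------
# network weight recount

def recount_fusion_weight(architectures: dict) -> int:
    """Sum over proteins of distinct adjacent domain pairs (canonical
    endpoint order), recomputed directly from architecture strings."""
    total = 0
    for arch in architectures.values():
        domains = arch.split("+") if isinstance(arch, str) else list(arch.domains)
        if domains == ["unknown"]:
            domains = []
        pairs = {
            tuple(sorted((domains[i], domains[i + 1])))
            for i in range(len(domains) - 1)
        }
        total += len(pairs)
    return total


def recount_neighborhood_weight(architectures: dict, operons) -> int:
    """Sum over operons of distinct cross-gene domain pairs."""
    def doms(gid):
        arch = architectures.get(gid)
        if arch is None:
            return ["unknown"]
        d = arch.split("+") if isinstance(arch, str) else list(arch.domains)
        return d if d else ["unknown"]

    total = 0
    for op in operons:
        pairs = set()
        gene_domains = [doms(g) for g in op.gene_ids]
        for i in range(len(gene_domains)):
            for j in range(i + 1, len(gene_domains)):
                for a in gene_domains[i]:
                    for b in gene_domains[j]:
                        pairs.add(tuple(sorted((a, b))))
        total += len(pairs)
    return total


# --------------------------------------------------------------------------
# LSE rule, evaluated directly per cell

def oracle_lse_cells(matrix, min_copies: int, min_fold: float):
    """(family, taxon) cells satisfying the expansion rule, by direct
    evaluation with statistics.median."""
    import statistics

    flagged = []
    for family in matrix.index:
        for taxon in matrix.columns:
            count = int(matrix.loc[family, taxon])
            others = [int(matrix.loc[family, t]) for t in matrix.columns if t != taxon]
            med = statistics.median(others)
            if count >= min_copies and (med == 0 or count >= min_fold * med):
                flagged.append((str(family), str(taxon)))
    return sorted(flagged)
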