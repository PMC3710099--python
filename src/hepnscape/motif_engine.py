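"""Detection and classification of the HEPN Rx4-6H active-site motif.

The catalytic signature of HEPN-like endoRNases is an arginine followed,
after a spacer of 4-6 residues, by a histidine (Rx4-6H; the 4-residue
spacer is typical, 6 occurs in some families, and 5 is accepted as part
of the printed range).  Supporting features are a polar residue
immediately after the R (preferentially N, D or H) and an upstream
Ex3[KR] element carrying a second conserved acidic residue.  Families in
which the canonical H is absent may instead use a strongly conserved
histidine N-terminal to the motif as an alternative active site, while
domains lacking conserved charged/polar residues altogether are
classified as catalytically inactive RNA-binding versions.

Column conservation and the consensus line use the residue classes
h (hydrophobic) = WFYMLIVACTH, p (polar) = EDKRNQHTS and
s (small) = ACDGNPSTV; the classes overlap (H and T are both
hydrophobic and polar) and precedence h > p > s breaks ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from hepnscape.genome_io import Alignment

HYDROPHOBIC = frozenset("WFYMLIVACTH")
POLAR = frozenset("EDKRNQHTS")
SMALL = frozenset("ACDGNPSTV")
#: residues preferred immediately after the catalytic R
POLAR_AFTER_R_PREFERRED = frozenset("NDH")

RESIDUE_CLASSES: dict[str, frozenset] = {
    "h": HYDROPHOBIC,
    "p": POLAR,
    "s": SMALL,
}
#: fixed precedence when several classes reach the consensus threshold
CLASS_PRECEDENCE = ("h", "p", "s")

DEFAULT_CONSERVATION = 0.8


@dataclass(frozen=True)
class MotifHit:
    """One located R-x{4..6}-H site in an ungapped sequence."""

    r_pos: int
    spacer: int
    h_pos: int
    polar_after_r: bool
    #: True when the post-R residue is in the preferred {N, D, H} set
    #: (as opposed to merely in the broad polar class)
    polar_preferred: bool = False
    upstream_exkr_pos: int | None = None

    def __post_init__(self) -> None:
        if self.h_pos != self.r_pos + self.spacer + 1:
            raise ValueError("h_pos must equal r_pos + spacer + 1")
        if not 4 <= self.spacer <= 6:
            raise ValueError("spacer must be in [4, 6]")


@dataclass(frozen=True)
class ActivityCall:
    """Classification of a domain/family as active or inactive."""

    call: str  # active_canonical | active_alternative | inactive_binding
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = {"active_canonical", "active_alternative", "inactive_binding"}
        if self.call not in allowed:
            raise ValueError(f"unknown call {self.call!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")


def _find_upstream_exkr(seq: str, r_pos: int) -> int | None:
    """Last E-x{3}-[KR] whose basic residue lies N-terminal to ``r_pos``."""
    best = None
    for i in range(r_pos - 4):
        if seq[i] == "E" and seq[i + 4] in "KR" and i + 4 < r_pos:
            best = i
    return best


def scan_rxh(seq: str, min_spacer: int = 4, max_spacer: int = 6) -> list[MotifHit]:
    """Report every R-x{spacer}-H site in an ungapped sequence.

    Overlapping hits (e.g. one R pairing with H at both spacer 4 and 6)
    are all reported.  Hits are ordered by (r_pos, spacer).
    """
    if "-" in seq or "." in seq:
        raise ValueError(
            "gapped sequence: degap rows and use classify_active_site for alignments"
        )
    seq = seq.upper()
    hits = []
    for i, aa in enumerate(seq):
        if aa != "R":
            continue
        for spacer in range(min_spacer, max_spacer + 1):
            j = i + spacer + 1
            if j < len(seq) and seq[j] == "H":
                after = seq[i + 1]
                preferred = after in POLAR_AFTER_R_PREFERRED
                hits.append(
                    MotifHit(
                        r_pos=i,
                        spacer=spacer,
                        h_pos=j,
                        polar_after_r=preferred or after in POLAR,
                        polar_preferred=preferred,
                        upstream_exkr_pos=_find_upstream_exkr(seq, i),
                    )
                )
    return hits


def column_conservation(alignment: Alignment, column: int) -> tuple[str, float]:
    """Most frequent non-gap residue in a column and its fraction.

    The fraction is over non-gap rows; ties break lexicographically.
    A gap-only column returns ('-', 0.0).
    """
    col = alignment.column(column)
    residues = [c for c in col if c != "-"]
    if not residues:
        return "-", 0.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    top = min(counts, key=lambda c: (-counts[c], c))
    return top, counts[top] / len(residues)


def consensus_line(alignment: Alignment, threshold: float = 0.7) -> str:
    """Per-column consensus: residue letter, class code (h/p/s) or '.'.

    A column gets its top residue letter if that residue reaches the
    threshold among non-gap rows; otherwise the first residue class
    (precedence h > p > s) whose members jointly reach the threshold;
    otherwise '.'.  Gap-only columns yield '.'.
    """
    out = []
    for i in range(alignment.width):
        col = [c for c in alignment.column(i) if c != "-"]
        if not col:
            out.append(".")
            continue
        top, frac = column_conservation(alignment, i)
        if frac >= threshold:
            out.append(top)
            continue
        for code in CLASS_PRECEDENCE:
            members = RESIDUE_CLASSES[code]
            if sum(1 for c in col if c in members) / len(col) >= threshold:
                out.append(code)
                break
        else:
            out.append(".")
    return "".join(out)


@dataclass
class _ColumnMap:
    """Maps a degapped row position back to its alignment column."""

    row: str
    cols: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cols = [i for i, c in enumerate(self.row) if c != "-"]


def _conserved_columns(
    alignment: Alignment, residues: frozenset | set | str, threshold: float
) -> list[int]:
    """Columns where membership of ``residues`` reaches ``threshold``."""
    residues = set(residues)
    out = []
    for i in range(alignment.width):
        col = [c for c in alignment.column(i) if c != "-"]
        if col and sum(1 for c in col if c in residues) / len(col) >= threshold:
            out.append(i)
    return out


def classify_active_site(
    target: Alignment | str,
    family_hits: list[MotifHit] | None = None,
    conservation_threshold: float = DEFAULT_CONSERVATION,
    min_spacer: int = 4,
    max_spacer: int = 6,
) -> ActivityCall:
    """Classify a family alignment (or a single sequence) by active-site state.

    * ``active_canonical`` — an Rx4-6H site is present and, in alignment
      mode, both its R and H columns are conserved at or above the
      threshold (default 0.8).
    * ``active_alternative`` — no conserved canonical site, but a
      conserved H column lies N-terminal to a conserved basic-residue
      (K/R) column: the displaced-histidine configuration.
    * ``inactive_binding`` — no conserved charged/polar catalytic
      columns (R, H, E, K, D) at all: a presumed RNA-binding version.

    The Ex3[KR] element and the polar residue after R are recorded as
    evidence but are not required for an active call.
    """
    if isinstance(target, str):
        if not target:
            raise ValueError("empty sequence")
        hits = family_hits if family_hits is not None else scan_rxh(
            target, min_spacer, max_spacer
        )
        if hits:
            ev = [f"Rx{hits[0].spacer}H site at R={hits[0].r_pos}"]
            if hits[0].polar_after_r:
                ev.append("polar residue after R")
            if hits[0].upstream_exkr_pos is not None:
                ev.append(f"upstream Ex3[KR] at {hits[0].upstream_exkr_pos}")
            return ActivityCall("active_canonical", tuple(ev))
        h_positions = [i for i, c in enumerate(target) if c == "H"]
        basic = [i for i, c in enumerate(target) if c in "KR"]
        if h_positions and basic and min(h_positions) < max(basic):
            return ActivityCall(
                "active_alternative",
                (f"H at {min(h_positions)} N-terminal to basic residue",),
            )
        return ActivityCall(
            "inactive_binding", ("no catalytic R/H arrangement found",)
        )

    aln = target
    if aln.width == 0:
        raise ValueError("empty alignment region")
    n_rows = len(aln)
    # map per-row motif hits to alignment columns and count support
    site_support: dict[tuple[int, int], int] = {}
    for row in aln.rows:
        cmap = _ColumnMap(row)
        degapped = row.replace("-", "")
        if not degapped:
            continue
        for hit in scan_rxh(degapped, min_spacer, max_spacer):
            key = (cmap.cols[hit.r_pos], cmap.cols[hit.h_pos])
            site_support[key] = site_support.get(key, 0) + 1
    nongap_rows = sum(1 for row in aln.rows if row.replace("-", ""))
    for (r_col, h_col), support in sorted(site_support.items()):
        if nongap_rows and support / nongap_rows >= conservation_threshold:
            r_top, r_frac = column_conservation(aln, r_col)
            h_top, h_frac = column_conservation(aln, h_col)
            if (
                r_top == "R"
                and h_top == "H"
                and r_frac >= conservation_threshold
                and h_frac >= conservation_threshold
            ):
                ev = [
                    f"conserved R column {r_col} ({r_frac:.2f})",
                    f"conserved H column {h_col} ({h_frac:.2f})",
                ]
                return ActivityCall("active_canonical", tuple(ev))
    # alternative site: conserved H column N-terminal to a conserved basic column
    h_cols = [
        c
        for c in _conserved_columns(aln, {"H"}, conservation_threshold)
    ]
    basic_cols = _conserved_columns(aln, {"K", "R"}, conservation_threshold)
    for h_col in h_cols:
        later_basic = [c for c in basic_cols if c > h_col]
        if later_basic:
            return ActivityCall(
                "active_alternative",
                (
                    f"conserved H column {h_col} N-terminal to basic column "
                    f"{later_basic[0]}",
                ),
            )
    charged_polar_cols = _conserved_columns(
        aln, {"R", "H", "E", "K", "D"}, conservation_threshold
    )
    if not charged_polar_cols:
        return ActivityCall(
            "inactive_binding",
            ("no conserved charged/polar columns in scanned region",),
        )
    return ActivityCall(
        "inactive_binding",
        (
            "conserved charged/polar columns present but no catalytic "
            "R/H arrangement",
        ),
    )
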