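"""Domain annotation and N->C architecture strings.

A domain library holds named detectors of three kinds: exact sentinel
subsequences (used by the synthetic genomes), position-weight matrices
scored as summed per-position log-odds over a sliding window, and
regular-expression motif patterns.  Real profile-HMM search is out of
scope; externally produced domain intervals can be imported from TSV
instead (``read_domain_tsv``).

Overlapping hits are resolved greedily: best score wins, ties broken by
earliest start then domain name; losing hits are dropped, not trimmed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DomainAnnotation:
    """A located domain on a protein; 0-based half-open residue interval."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.domain_name}@{self.protein_id}: bad interval "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Architecture:
    """Ordered N->C domain names of one protein, e.g. 'MNT+HEPN'."""

    protein_id: str
    domains: tuple[str, ...]

    @property
    def string(self) -> str:
        return "+".join(self.domains) if self.domains else "unknown"


@dataclass
class DomainLibraryEntry:
    """One named detector.

    ``detector`` is 'sentinel', 'pwm' or 'pattern'.  For sentinels,
    ``sentinel`` is the exact subsequence; for PWMs, ``pwm`` maps each
    residue to a list of per-position log-odds and ``cutoff`` is the
    minimal window score; for patterns, ``pattern`` is a residue regex.
    """

    name: str
    detector: str
    sentinel: str | None = None
    pwm: dict[str, list[float]] | None = None
    cutoff: float = 0.0
    pattern: str | None = None
    min_length: int = 1

    def __post_init__(self) -> None:
        if self.detector not in {"sentinel", "pwm", "pattern"}:
            raise ValueError(f"unknown detector type {self.detector!r}")
        if self.detector == "sentinel" and not self.sentinel:
            raise ValueError(f"{self.name}: sentinel detector needs a sentinel")
        if self.detector == "pattern" and not self.pattern:
            raise ValueError(f"{self.name}: pattern detector needs a pattern")
        if self.detector == "pwm":
            if not self.pwm:
                raise ValueError(f"{self.name}: pwm detector needs a matrix")
            widths = {len(v) for v in self.pwm.values()}
            if len(widths) != 1:
                raise ValueError(f"{self.name}: ragged PWM columns")

    @property
    def width(self) -> int:
        if self.detector == "sentinel":
            return len(self.sentinel)
        if self.detector == "pwm":
            return len(next(iter(self.pwm.values())))
        raise ValueError("pattern detectors have no fixed width")


@dataclass
class DomainLibrary:
    entries: list[DomainLibraryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate domain names in library")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainLibrary":
        """Load a library from a YAML config of the form
        ``domains: [{name, detector, sentinel|pwm+cutoff|pattern}, ...]``."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        entries = [DomainLibraryEntry(**d) for d in cfg.get("domains", [])]
        return cls(entries=entries)


def _sentinel_hits(seq: str, entry: DomainLibraryEntry, protein_id: str):
    needle = entry.sentinel
    start = seq.find(needle)
    while start != -1:
        yield DomainAnnotation(
            protein_id, entry.name, start, start + len(needle), float(len(needle))
        )
        start = seq.find(needle, start + 1)  # overlapping occurrences included


def _pwm_hits(seq: str, entry: DomainLibraryEntry, protein_id: str):
    w = entry.width
    for start in range(len(seq) - w + 1):
        score = 0.0
        ok = True
        for k in range(w):
            col = entry.pwm.get(seq[start + k])
            if col is None:
                ok = False
                break
            score += col[k]
        if ok and score >= entry.cutoff:
            yield DomainAnnotation(protein_id, entry.name, start, start + w, score)


def _pattern_hits(seq: str, entry: DomainLibraryEntry, protein_id: str):
    # lookahead so overlapping matches are all found
    rx = re.compile(f"(?=({entry.pattern}))")
    for m in rx.finditer(seq):
        span = len(m.group(1))
        if span >= entry.min_length:
            yield DomainAnnotation(
                protein_id, entry.name, m.start(), m.start() + span, float(span)
            )


def annotate_protein(
    seq: str, library: DomainLibrary, protein_id: str = "protein"
) -> list[DomainAnnotation]:
    """All above-cutoff detector hits, with overlaps resolved.

    Hits are collected from every library entry, then filtered greedily
    by descending score / ascending start / domain name; a hit is kept
    only if it does not overlap an already-kept one.  The result is
    sorted by start coordinate.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(library) == 0:
        raise ValueError("empty domain library")
    seq = seq.upper()
    raw: list[DomainAnnotation] = []
    for entry in library:
        if entry.detector == "sentinel":
            raw.extend(_sentinel_hits(seq, entry, protein_id))
        elif entry.detector == "pwm":
            raw.extend(_pwm_hits(seq, entry, protein_id))
        else:
            raw.extend(_pattern_hits(seq, entry, protein_id))
    raw.sort(key=lambda h: (-h.score, h.start, h.domain_name))
    kept: list[DomainAnnotation] = []
    for hit in raw:
        if all(hit.end <= k.start or hit.start >= k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def architecture_string(annotations: Sequence[DomainAnnotation]) -> str:
    """'+'-joined domain names in N->C order; 'unknown' when empty."""
    if not annotations:
        return "unknown"
    ordered = sorted(annotations, key=lambda a: a.start)
    return "+".join(a.domain_name for a in ordered)


def fusion_pairs(architecture: Architecture | str) -> list[tuple[str, str]]:
    """Consecutive N->C domain pairs of a fusion protein.

    'A+B+C' yields (A,B) and (B,C) but never (A,C): only adjacent
    domains in the same polypeptide are counted.  Repeats such as HEPN
    dyads ('A+A') yield the self-pair (A,A).
    """
    if isinstance(architecture, Architecture):
        domains = architecture.domains
    else:
        domains = () if architecture == "unknown" else tuple(architecture.split("+"))
    return list(zip(domains, domains[1:]))


def read_domain_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Import externally produced domain intervals.

    Expects a header line ``protein_id  domain  start  end  score``
    (tab-separated, 0-based half-open coordinates).
    """
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["protein_id", "domain", "start", "end", "score"]
        if header[: len(required)] != required:
            raise ValueError(f"unexpected domain TSV header {header!r} in {path}")
        for line in fh:
            if not line.strip():
                continue
            pid, dom, start, end, score = line.rstrip("\n").split("\t")[:5]
            out.append(DomainAnnotation(pid, dom, int(start), int(end), float(score)))
    return out
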