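"""Phyletic patterns and lineage-specific expansions (LSEs).

A phyletic matrix tallies copies of each family per taxon (taxon =
genome/assembly identifier; higher ranks via a user-supplied lineage
map).  An LSE is flagged when one taxon's copy number is both large in
absolute terms and large relative to the median over the other taxa —
the pattern exemplified by a 46-copy expansion against a background of
one or two copies elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

DEFAULT_MIN_COPIES = 10
DEFAULT_MIN_FOLD = 5.0


@dataclass(frozen=True)
class LSECall:
    taxon: str
    family: str
    copy_count: int
    background_median: float


def build_matrix(assignments: Mapping[str, tuple[str, str]]) -> pd.DataFrame:
    """Tally a family-by-taxon copy-number matrix.

    ``assignments`` maps gene id -> (family, taxon); each gene counts
    once.  Rows are families, columns taxa, both sorted
    lexicographically.  Empty input gives an empty (0x0) frame.
    """
    if not assignments:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(
        [(fam, tax) for fam, tax in assignments.values()],
        columns=["family", "taxon"],
    )
    mat = df.groupby(["family", "taxon"]).size().unstack(fill_value=0)
    return mat.sort_index(axis=0).sort_index(axis=1).astype(int)


def presence_absence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Project copy numbers to a boolean presence/absence matrix."""
    return matrix > 0


def rollup(matrix: pd.DataFrame, lineage_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum taxon columns into higher-rank lineages.

    Taxa missing from the map keep their own name.
    """
    if matrix.empty:
        return matrix
    renamed = matrix.rename(columns=lambda t: lineage_map.get(t, t))
    return renamed.T.groupby(level=0).sum().T.sort_index(axis=1)


def detect_lse(
    matrix: pd.DataFrame,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> list[LSECall]:
    """Flag lineage-specific expansions.

    A (family, taxon) cell is flagged when its copy count is at least
    ``min_copies`` and at least ``min_fold`` times the median count of
    that family over all *other* taxa; a background median of zero
    satisfies the fold rule.  Requires >= 2 taxa (no background
    otherwise).  Calls are ordered by (family, taxon).
    """
    if matrix.shape[1] < 2:
        raise ValueError("LSE detection needs at least two taxa for a background")
    calls = []
    for family in matrix.index:
        row = matrix.loc[family]
        for taxon in matrix.columns:
            count = int(row[taxon])
            if count < min_copies:
                continue
            background = row.drop(taxon)
            med = float(background.median())
            if med == 0.0 or count >= min_fold * med:
                calls.append(
                    LSECall(
                        taxon=str(taxon),
                        family=str(family),
                        copy_count=count,
                        background_median=med,
                    )
                )
    return sorted(calls, key=lambda c: (c.family, c.taxon))
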