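"""Per-column conservation classification of a multiple alignment.

Implements the four-way Clustal symbol scheme — identical (*), strongly
conserved (:), weakly conserved (.) and non-conserved (space) — using the
canonical ClustalX amino-acid groups, and maps column categories onto the
ungapped coordinates of a chosen reference row. A Shannon column entropy is
provided as a simple continuous variability score.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .sequences import AA_SYMBOLS, GAP, SequenceRecord

# Canonical ClustalX conservation groups.
STRONG_GROUPS = [frozenset(g) for g in
                 ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")]
WEAK_GROUPS = [frozenset(g) for g in
               ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
                "NDEQHK", "NEQHRK", "FVLIM", "HFY")]


class ConservationCategory(str, Enum):
    IDENTICAL = "identical"
    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"

    @property
    def symbol(self) -> str:
        return {"identical": "*", "strong": ":", "weak": ".", "none": " "}[self.value]


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: ≥2 equal-length gapped rows."""

    rows: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r.seq) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].seq)

    def column(self, i: int) -> list[str]:
        return [r.seq[i] for r in self.rows]

    def row(self, ref_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == ref_id:
                return r
        raise KeyError(f"sequence {ref_id!r} not in alignment")


def classify_column(residues: Sequence[str]) -> ConservationCategory:
    """Classify one alignment column.

    Precedence: identical > strong > weak > none. Any gap in the column makes
    it non-conserved, matching typical Clustal symbol output.
    """
    if len(residues) < 2:
        raise ValueError("need at least 2 symbols")
    syms = [s.upper() for s in residues]
    for s in syms:
        if s != GAP and s not in AA_SYMBOLS:
            raise ValueError(f"invalid residue symbol {s!r}")
    if GAP in syms:
        return ConservationCategory.NONE
    uniq = set(syms)
    if len(uniq) == 1:
        return ConservationCategory.IDENTICAL
    if any(uniq <= g for g in STRONG_GROUPS):
        return ConservationCategory.STRONG
    if any(uniq <= g for g in WEAK_GROUPS):
        return ConservationCategory.WEAK
    return ConservationCategory.NONE


def conservation_profile(aln: Alignment) -> str:
    """Symbol string ('* : . ␣') with one character per alignment column."""
    return "".join(classify_column(aln.column(i)).symbol for i in range(aln.n_cols))


def categories(aln: Alignment) -> list[ConservationCategory]:
    return [classify_column(aln.column(i)) for i in range(aln.n_cols)]


def map_to_reference(aln: Alignment, ref_id: str) -> dict[int, ConservationCategory]:
    """Column categories re-indexed to 1-based ungapped reference positions.

    Columns where the reference row carries a gap are skipped, so the map has
    exactly one entry per reference residue.
    """
    ref = aln.row(ref_id)
    cats = categories(aln)
    out: dict[int, ConservationCategory] = {}
    pos = 0
    for col, sym in enumerate(ref.seq):
        if sym == GAP:
            continue
        pos += 1
        out[pos] = cats[col]
    return out


def column_entropy(residues: Sequence[str]) -> float:
    """Shannon entropy (bits) of residue frequencies over non-gap symbols."""
    syms = [s.upper() for s in residues if s != GAP]
    if len(syms) < 2:
        raise ValueError("need at least 2 non-gap symbols")
    counts = Counter(syms)
    n = len(syms)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def profile_table(aln: Alignment) -> list[tuple[int, str, str]]:
    """(1-based column, column residues joined, category name) rows for TSV export."""
    rows = []
    for i in range(aln.n_cols):
        col = aln.column(i)
        rows.append((i + 1, "".join(col), classify_column(col).value))
    return rows
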