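"""Conservation × solvent-accessibility × interaction-role cross-tabulation.

Joins three per-residue annotations on reference numbering — the conservation
category from a multiple alignment, the side-chain accessibility class from a
structure, and the interaction role (lipid-binding, protein–protein interface
or non-interacting) — and computes the summary statistics of the variability
analysis: 4×3 count matrices per role scope, identity fractions per role, and
the share of sequence differences attributable to non-interacting positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .conservation import ConservationCategory
from .structure import ASAClass, ASAEntry

CATEGORY_ORDER = [c.value for c in ConservationCategory]
CLASS_ORDER = [c.value for c in ASAClass]


class Role(str, Enum):
    LIPID = "lipid"
    PPI = "ppi"
    NONE = "none"


@dataclass(frozen=True)
class ResidueRecord:
    position: int
    residue: str
    role: Role
    category: ConservationCategory
    asa_ratio: float
    asa_class: ASAClass


@dataclass(frozen=True)
class JoinResult:
    records: list[ResidueRecord]
    missing_from_structure: list[int]


def read_roles(path: str | Path) -> dict[int, Role]:
    """Read a two-column TSV (position, role) of interaction annotations."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["position", "role"], header=None, dtype=str)
    if df["position"].iloc[0].lower() == "position":
        df = df.iloc[1:]
    return {int(p): Role(r.strip().lower()) for p, r in zip(df["position"], df["role"])}


def build_records(conservation_map: dict[int, ConservationCategory],
                  asa_entries: list[ASAEntry] | dict[int, ASAEntry],
                  roles: dict[int, Role],
                  reference_seq: str | None = None) -> JoinResult:
    """Inner-join the three annotations on 1-based reference positions.

    Every conservation-map position must carry a role (the role table covers
    the full reference); positions without structure coverage are collected in
    ``missing_from_structure`` rather than silently dropped.
    """
    if isinstance(asa_entries, list):
        asa_by_pos = {e.residue_number: e for e in asa_entries}
    else:
        asa_by_pos = dict(asa_entries)
    missing_roles = sorted(set(conservation_map) - set(roles))
    if missing_roles:
        raise ValueError(f"positions without role annotation: {missing_roles[:10]}"
                         f"{'...' if len(missing_roles) > 10 else ''}")
    records, missing = [], []
    for pos in sorted(conservation_map):
        if pos not in asa_by_pos:
            missing.append(pos)
            continue
        entry = asa_by_pos[pos]
        residue = reference_seq[pos - 1] if reference_seq else "X"
        records.append(ResidueRecord(position=pos, residue=residue, role=roles[pos],
                                     category=conservation_map[pos],
                                     asa_ratio=entry.ratio, asa_class=entry.asa_class))
    return JoinResult(records=records, missing_from_structure=missing)


def crosstab(records: list[ResidueRecord], role_filter: str = "all") -> pd.DataFrame:
    """4×3 count matrix (conservation category × ASA class) under a role scope.

    ``role_filter``: "all", "none" (non-interacting only), "lipid", "ppi",
    or "interacting" (lipid + ppi).
    """
    if role_filter == "all":
        recs = records
    elif role_filter == "interacting":
        recs = [r for r in records if r.role is not Role.NONE]
    else:
        role = Role(role_filter)
        recs = [r for r in records if r.role is role]
    tab = pd.DataFrame(0, index=CATEGORY_ORDER, columns=CLASS_ORDER, dtype=int)
    for r in recs:
        tab.loc[r.category.value, r.asa_class.value] += 1
    return tab


def identity_fraction_by_role(records: list[ResidueRecord], role: Role | str) -> float:
    """Percent of positions with a given role whose column is strictly identical."""
    role = Role(role)
    in_role = [r for r in records if r.role is role]
    if not in_role:
        raise ValueError(f"no records with role {role.value!r}")
    n_ident = sum(r.category is ConservationCategory.IDENTICAL for r in in_role)
    return 100.0 * n_ident / len(in_role)


def variability_attribution(records: list[ResidueRecord],
                            conserved_categories: tuple[str, ...] = ("identical",)) -> dict:
    """Share of varying positions that fall on non-interacting residues.

    A position is "varying" when its conservation category is outside
    ``conserved_categories`` (default: anything not strictly identical). The
    returned pct is rounded to the nearest integer, matching how such
    attributions are normally quoted.
    """
    conserved = {ConservationCategory(c) for c in conserved_categories}
    varying = [r for r in records if r.category not in conserved]
    if not varying:
        raise ValueError("no varying residues")
    non_int = [r for r in varying if r.role is Role.NONE]
    pct = round(100.0 * len(non_int) / len(varying))
    return {"n_varying_total": len(varying),
            "n_varying_noninteracting": len(non_int),
            "pct": int(pct)}


def attribution_from_counts(n_varying_total: int, n_varying_noninteracting: int) -> int:
    """Attribution percentage straight from two counts (e.g. published totals)."""
    if n_varying_total <= 0 or not 0 <= n_varying_noninteracting <= n_varying_total:
        raise ValueError("invalid counts")
    return round(100.0 * n_varying_noninteracting / n_varying_total)


def summarize(records: list[ResidueRecord]) -> dict:
    """Headline numbers in both conservation binnings.

    Because published summaries rarely state whether weakly conserved columns
    count as "conserved", both binnings are reported: strict (non-conserved =
    category none) and loose (non-conserved = weak or none).
    """
    out: dict = {"n_records": len(records)}
    for scope in ("all", "none", "lipid", "ppi", "interacting"):
        out[f"crosstab_{scope}"] = crosstab(records, scope).to_dict()
    for role in Role:
        try:
            out[f"identity_pct_{role.value}"] = identity_fraction_by_role(records, role)
        except ValueError:
            out[f"identity_pct_{role.value}"] = None
    for label, conserved in (("strict", ("identical",)),
                             ("loose", ("identical", "strong", "weak"))):
        try:
            out[f"attribution_{label}"] = variability_attribution(
                records, conserved_categories=("identical",) if label == "strict"
                else ("identical", "strong", "weak"))
        except ValueError:
            out[f"attribution_{label}"] = None
    return out
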