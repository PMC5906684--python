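"""Aromatic-cage conservation profiles for chromo-like domain families.

Chromo-like SH3-fold domains (chromo, Tudor, MBT, PWWP, BAH, ...) read
methylated lysine/arginine marks through a cage of ~5 aromatic side chains
(Y, W, F, H) making cation-π contacts with the methylated amino group. Given
a family alignment and the five cage columns (located on an annotated
reference, e.g. a chromo domain structure), this module computes the
per-position fraction of aromatic residues — the family-level conservation
statistic used to compare cage retention across families.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import Alignment, GAP
from .knuckles import AROMATIC

__all__ = [
    "CageSpec",
    "CageProfile",
    "map_cage_columns",
    "aromatic_fraction_profile",
    "compare_families",
]

N_CAGE_POSITIONS = 5


@dataclass(frozen=True)
class CageSpec:
    """Five alignment columns (1-based, strictly increasing) holding the cage."""

    columns: tuple[int, int, int, int, int]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.columns) != N_CAGE_POSITIONS:
            raise ValueError("exactly 5 cage columns are required")
        if any(c < 1 for c in self.columns):
            raise ValueError("cage columns are 1-based")
        if list(self.columns) != sorted(set(self.columns)):
            raise ValueError("cage columns must be strictly increasing")


@dataclass(frozen=True)
class CageProfile:
    """Aromatic fractions and column coverage at the five cage positions."""

    family_label: str
    fractions: tuple[float, ...]
    coverage: tuple[float, ...]
    n_sequences: int

    def __post_init__(self) -> None:
        for name in ("fractions", "coverage"):
            vals = getattr(self, name)
            if len(vals) != N_CAGE_POSITIONS or any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} must be 5 values in [0, 1]")


def map_cage_columns(aln: Alignment, reference_id: str,
                     reference_positions: tuple[int, int, int, int, int],
                     source: str = "") -> CageSpec:
    """Convert ungapped residue positions of a reference row into alignment columns."""
    ref = next((r for r in aln.records if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    # residue index (1-based, gaps skipped) -> alignment column (1-based)
    residue_to_column: dict[int, int] = {}
    res_idx = 0
    for col, ch in enumerate(ref.residues, start=1):
        if ch != GAP:
            res_idx += 1
            residue_to_column[res_idx] = col
    columns = []
    for pos in reference_positions:
        if pos not in residue_to_column:
            raise ValueError(
                f"position {pos} beyond ungapped length {res_idx} of reference {reference_id!r}"
            )
        columns.append(residue_to_column[pos])
    return CageSpec(columns=tuple(columns), source=source or f"mapped from {reference_id}")


def aromatic_fraction_profile(aln: Alignment, cage: CageSpec,
                              include_gapped_rows: bool = False) -> CageProfile:
    """Fraction of aromatic residues (Y, W, F, H) at each cage column.

    By default the denominator is the number of rows with a residue at the
    column (gaps excluded); ``include_gapped_rows`` switches to the total row
    count. Coverage (non-gap fraction) is always reported so the choice is
    auditable. An all-gap column yields fraction 0 and coverage 0.
    """
    if any(c > aln.n_columns for c in cage.columns):
        raise ValueError(f"cage columns {cage.columns} exceed alignment width {aln.n_columns}")
    fractions, coverage = [], []
    for col in cage.columns:
        residues = [ch for ch in aln.column(col) if ch != GAP]
        n_aromatic = sum(1 for ch in residues if ch in AROMATIC)
        denom = aln.n_rows if include_gapped_rows else len(residues)
        fractions.append(n_aromatic / denom if denom else 0.0)
        coverage.append(len(residues) / aln.n_rows)
    return CageProfile(family_label=aln.family_label, fractions=tuple(fractions),
                       coverage=tuple(coverage), n_sequences=aln.n_rows)


def compare_families(profiles: list[CageProfile]) -> pd.DataFrame:
    """Long-format table (family, position, fraction, coverage, n_sequences)."""
    if not profiles:
        raise ValueError("need at least one profile")
    rows = [
        {
            "family": p.family_label,
            "position": pos,
            "fraction": p.fractions[pos - 1],
            "coverage": p.coverage[pos - 1],
            "n_sequences": p.n_sequences,
        }
        for p in profiles
        for pos in range(1, N_CAGE_POSITIONS + 1)
    ]
    return pd.DataFrame(rows, columns=["family", "position", "fraction", "coverage", "n_sequences"])
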