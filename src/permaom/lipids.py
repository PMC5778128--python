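"""GDGT membrane-lipid biomarker indices.

Glycerol dialkyl glycerol tetraethers (GDGTs) fingerprint the source
community of sedimentary organic matter. Two standard ratios are computed
from integrated abundances (arbitrary response units — all indices are
scale-invariant):

* BIT index — branched (terrestrial bacterial) vs. isoprenoid tetraethers;
  values near 1 indicate terrestrial organic-matter dominance::

      BIT = (brGDGT-I + brGDGT-II + brGDGT-III)
            / (brGDGT-I + brGDGT-II + brGDGT-III + crenarchaeol)

* Methane index (MI) — elevated (→1) where AOM archaea dominate the
  isoprenoid tetraether pool, as in a sulfate–methane transition zone::

      MI = (GDGT-1 + GDGT-2 + GDGT-3)
           / (GDGT-1 + GDGT-2 + GDGT-3 + crenarchaeol + crenarchaeol′)

plus the plain archaeal:bacterial ether-lipid ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import UndefinedIndexError, ValidationError

__all__ = [
    "GdgtMeasurement",
    "bit_index",
    "methane_index",
    "archaeal_bacterial_ratio",
    "batch_indices",
]

_FIELDS = (
    "br_I", "br_II", "br_III",
    "gdgt_1", "gdgt_2", "gdgt_3",
    "crenarchaeol", "cren_isomer",
    "archaeal_ether_sum", "bacterial_ether_sum",
)


@dataclass(frozen=True)
class GdgtMeasurement:
    """Integrated GDGT / ether-lipid abundances for one sample."""

    br_I: float = 0.0
    br_II: float = 0.0
    br_III: float = 0.0
    gdgt_1: float = 0.0
    gdgt_2: float = 0.0
    gdgt_3: float = 0.0
    crenarchaeol: float = 0.0
    cren_isomer: float = 0.0
    archaeal_ether_sum: float = 0.0
    bacterial_ether_sum: float = 0.0

    def __post_init__(self) -> None:
        for name in _FIELDS:
            if getattr(self, name) < 0.0:
                raise ValidationError(
                    f"{name} must be >= 0, got {getattr(self, name)!r}"
                )


def bit_index(m: GdgtMeasurement) -> float:
    """Branched vs. isoprenoid tetraether index, in [0, 1]."""
    branched = m.br_I + m.br_II + m.br_III
    denom = branched + m.crenarchaeol
    if denom == 0.0:
        raise UndefinedIndexError(
            "BIT undefined: branched GDGTs and crenarchaeol all zero"
        )
    return branched / denom


def methane_index(m: GdgtMeasurement) -> float:
    """Methane index over isoprenoid GDGTs, in [0, 1]."""
    methanogenic = m.gdgt_1 + m.gdgt_2 + m.gdgt_3
    denom = methanogenic + m.crenarchaeol + m.cren_isomer
    if denom == 0.0:
        raise UndefinedIndexError(
            "MI undefined: GDGT-1..3, crenarchaeol and its isomer all zero"
        )
    return methanogenic / denom


def archaeal_bacterial_ratio(m: GdgtMeasurement) -> float:
    """Archaeal to bacterial ether-lipid ratio (plain quotient, >= 0)."""
    if m.bacterial_ether_sum == 0.0:
        raise UndefinedIndexError(
            "archaeal:bacterial ratio undefined: bacterial ether sum is zero"
        )
    return m.archaeal_ether_sum / m.bacterial_ether_sum


def batch_indices(
    in_path: str | Path, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Compute all three indices for a CSV of measurements (one per row).

    Missing columns default to 0; an undefined index yields an empty cell
    rather than aborting the batch.
    """
    table = pd.read_csv(in_path)
    rows = []
    for _, row in table.iterrows():
        kwargs = {
            name: float(row[name])
            for name in _FIELDS
            if name in table.columns and pd.notna(row[name])
        }
        m = GdgtMeasurement(**kwargs)
        entry = {}
        for label, fn in (
            ("bit_index", bit_index),
            ("methane_index", methane_index),
            ("archaeal_bacterial_ratio", archaeal_bacterial_ratio),
        ):
            try:
                entry[label] = fn(m)
            except UndefinedIndexError:
                entry[label] = None
        rows.append(entry)
    out = pd.concat([table.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
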