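"""Depth-resolved pore-water geochemistry profiles.

A :class:`CoreProfile` holds the measured quantities of one sediment core as
an ordered sequence of :class:`HorizonRecord` objects: depth in metres below
seafloor (mbsf, positive downward), methane concentration (µmol per litre of
pore water), its carbon stable-isotope signature (δ¹³C-CH₄, ‰ VPDB), sulfate
(mM), nitrate / total manganese / total iron (µM), and a frozen-state flag
for ice-bonded permafrost intervals.

Profiles are exchanged as a single canonical CSV dialect::

    depth_mbsf,ch4_uM,d13c_ch4_permil,so4_mM,no3_uM,mn_uM,fe_uM,state

comma-separated, UTF-8, one header row, empty string = missing value.
``write_core_profile`` and ``read_core_profile`` are mutual inverses on valid
profiles, to full floating-point precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .errors import ProfileFormatError, ValidationError

__all__ = [
    "FrozenState",
    "HorizonRecord",
    "CoreProfile",
    "read_core_profile",
    "write_core_profile",
    "CSV_COLUMNS",
]

#: Canonical column order of the profile CSV dialect.
CSV_COLUMNS = (
    "depth_mbsf",
    "ch4_uM",
    "d13c_ch4_permil",
    "so4_mM",
    "no3_uM",
    "mn_uM",
    "fe_uM",
    "state",
)

#: Physically admissible range for δ¹³C-CH₄ on the VPDB scale (‰).
D13C_RANGE = (-120.0, 20.0)


class FrozenState(str, enum.Enum):
    """Cryostratigraphic state of a sediment horizon."""

    ICE_BONDED = "ice_bonded"
    UNFROZEN = "unfrozen"
    PARTIALLY_THAWED = "partially_thawed"
    UNKNOWN = "unknown"


def _check_nonneg(name: str, value: Optional[float]) -> None:
    if value is not None and not (value >= 0.0):
        raise ValidationError(f"{name} must be >= 0 when present, got {value!r}")


@dataclass(frozen=True)
class HorizonRecord:
    """One pore-water horizon.

    Concentrations are nullable: an empty cell in the source table means the
    analyte was not measured at that depth, not that it was absent.
    """

    depth_mbsf: float
    ch4: Optional[float] = None
    d13c_ch4: Optional[float] = None
    sulfate: Optional[float] = None
    nitrate: Optional[float] = None
    manganese: Optional[float] = None
    iron: Optional[float] = None
    frozen_state: FrozenState = FrozenState.UNKNOWN

    def __post_init__(self) -> None:
        if not math.isfinite(self.depth_mbsf):
            raise ValidationError(f"depth_mbsf must be finite, got {self.depth_mbsf!r}")
        _check_nonneg("ch4", self.ch4)
        _check_nonneg("sulfate", self.sulfate)
        _check_nonneg("nitrate", self.nitrate)
        _check_nonneg("manganese", self.manganese)
        _check_nonneg("iron", self.iron)
        if self.d13c_ch4 is not None and not (
            D13C_RANGE[0] <= self.d13c_ch4 <= D13C_RANGE[1]
        ):
            raise ValidationError(
                f"d13c_ch4 must lie in {D13C_RANGE} permil VPDB, got {self.d13c_ch4!r}"
            )
        if not isinstance(self.frozen_state, FrozenState):
            object.__setattr__(self, "frozen_state", FrozenState(self.frozen_state))


@dataclass(frozen=True)
class CoreProfile:
    """Depth-ordered pore-water records for one sediment core.

    Records must be strictly increasing in depth; duplicate depths are a
    validation error (replicate averaging is an upstream concern). Use
    :meth:`from_records` to sort unordered input.
    """

    core_id: str
    records: tuple[HorizonRecord, ...]
    inundation_age_yr: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if len(records) == 0:
            raise ValidationError("a CoreProfile requires at least one record")
        depths = [r.depth_mbsf for r in records]
        dupes = sorted({d for d in depths if depths.count(d) > 1})
        if dupes:
            raise ValidationError(f"duplicate depths in profile: {dupes}")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValidationError(
                "records must be strictly increasing in depth_mbsf; "
                "use CoreProfile.from_records to sort"
            )

    @classmethod
    def from_records(
        cls,
        core_id: str,
        records: Iterable[HorizonRecord],
        inundation_age_yr: Optional[float] = None,
        provenance: str = "",
    ) -> "CoreProfile":
        """Build a profile from records in any order (sorted by depth)."""
        ordered = tuple(sorted(records, key=lambda r: r.depth_mbsf))
        return cls(core_id, ordered, inundation_age_yr, provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HorizonRecord]:
        return iter(self.records)

    @property
    def depth_range(self) -> tuple[float, float]:
        return (self.records[0].depth_mbsf, self.records[-1].depth_mbsf)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view using the canonical column names."""
        rows = [
            {
                "depth_mbsf": r.depth_mbsf,
                "ch4_uM": r.ch4,
                "d13c_ch4_permil": r.d13c_ch4,
                "so4_mM": r.sulfate,
                "no3_uM": r.nitrate,
                "mn_uM": r.manganese,
                "fe_uM": r.iron,
                "state": r.frozen_state.value,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _cell(value: object) -> Optional[float]:
    """Missing cell -> None; otherwise a finite float."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        out = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ProfileFormatError(f"non-numeric cell {value!r}") from exc
    return out


def read_core_profile(path: str | Path, core_id: Optional[str] = None) -> CoreProfile:
    """Read a profile from the canonical CSV dialect.

    Rows are sorted by depth on read; missing cells become ``None``. The
    header must contain exactly the canonical columns (any order).

    Raises
    ------
    ProfileFormatError
        Unknown or missing header columns, or a non-numeric cell.
    ValidationError
        Duplicate depths, negative concentrations, out-of-range δ¹³C.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"state": "string"}, float_precision="round_trip")
    got = list(table.columns)
    unknown = [c for c in got if c not in CSV_COLUMNS]
    missing = [c for c in CSV_COLUMNS if c not in got]
    if unknown or missing:
        parts = []
        if missing:
            parts.append(f"missing column(s): {missing}")
        if unknown:
            parts.append(f"unknown column(s): {unknown}")
        raise ProfileFormatError("malformed header — " + "; ".join(parts))
    if len(table) == 0:
        raise ValidationError(f"profile file {path} contains no data rows")

    records = []
    for _, row in table.iterrows():
        state_raw = row["state"]
        if state_raw is None or pd.isna(state_raw) or str(state_raw).strip() == "":
            state = FrozenState.UNKNOWN
        else:
            try:
                state = FrozenState(str(state_raw).strip())
            except ValueError as exc:
                raise ProfileFormatError(
                    f"invalid state {state_raw!r}; expected one of "
                    f"{[s.value for s in FrozenState]}"
                ) from exc
        depth = _cell(row["depth_mbsf"])
        if depth is None:
            raise ProfileFormatError("empty depth_mbsf cell")
        records.append(
            HorizonRecord(
                depth_mbsf=depth,
                ch4=_cell(row["ch4_uM"]),
                d13c_ch4=_cell(row["d13c_ch4_permil"]),
                sulfate=_cell(row["so4_mM"]),
                nitrate=_cell(row["no3_uM"]),
                manganese=_cell(row["mn_uM"]),
                iron=_cell(row["fe_uM"]),
                frozen_state=state,
            )
        )
    return CoreProfile.from_records(core_id or path.stem, records)


def write_core_profile(profile: CoreProfile, path: str | Path) -> Path:
    """Write a profile in the canonical CSV dialect.

    Floats are written with Python's shortest round-tripping representation,
    so ``read_core_profile(write_core_profile(p))`` reproduces ``p``
    field-for-field. Output is byte-identical for identical inputs.
    """
    path = Path(path)

    def fmt(value: Optional[float]) -> str:
        return "" if value is None else repr(float(value))

    lines = [",".join(CSV_COLUMNS)]
    for r in profile.records:
        lines.append(
            ",".join(
                [
                    fmt(r.depth_mbsf),
                    fmt(r.ch4),
                    fmt(r.d13c_ch4),
                    fmt(r.sulfate),
                    fmt(r.nitrate),
                    fmt(r.manganese),
                    fmt(r.iron),
                    r.frozen_state.value,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
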