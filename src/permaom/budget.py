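"""Permafrost-degradation methane release and the oxidized-carbon budget.

As ice-bonded submarine permafrost degrades from the top at a rate
``v`` (m yr⁻¹), the methane held in its pore space is released into the
overlying thawed sediment. Upscaled over an area ``A`` (m²) with pore-water
volume fraction ``φ`` and pore-water methane concentration ``c``
(mol m⁻³ pore water), the release rate is::

    R = v · A · φ · c      [mol CH₄ yr⁻¹]

and the carbon consumed by anaerobic oxidation of a fraction f_ox of that
release is::

    B = R · f_ox · 12.011 g mol⁻¹ / 10¹² g Tg⁻¹   [Tg C yr⁻¹]

Defaults carry the two observed core degradation rates (0.006 and
0.053 m yr⁻¹) and the pan-Arctic submarine permafrost area of
3 × 10¹² m² (3 million km²). The pore-water volume fraction is an explicit,
always-echoed assumption (default 0.4): published pore-water concentrations
are per pore-water volume, and the water content used for upscaling
dominates the absolute budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .errors import ParameterError, ValidationError

__all__ = [
    "BudgetInputs",
    "BudgetResult",
    "methane_release_rate",
    "oxidized_carbon",
    "budget_grid",
    "grid_extremes",
    "budget_inputs_from_yaml",
    "CARBON_MOLAR_MASS_G_PER_MOL",
    "PAN_ARCTIC_SUBMARINE_PERMAFROST_M2",
    "DEGRADATION_RATE_C2_M_PER_YR",
    "DEGRADATION_RATE_BK2_M_PER_YR",
]

#: Molar mass of carbon (the C in CH₄), g mol⁻¹.
CARBON_MOLAR_MASS_G_PER_MOL = 12.011
#: Estimated pan-Arctic submarine permafrost area, m² (3 million km²).
PAN_ARCTIC_SUBMARINE_PERMAFROST_M2 = 3.0e12
#: Observed degradation rates for the two reference cores, m yr⁻¹.
DEGRADATION_RATE_C2_M_PER_YR = 0.006
DEGRADATION_RATE_BK2_M_PER_YR = 0.053

_LEVELS = ("low", "mean", "high")
_BOUNDS = ("min", "max")


@dataclass(frozen=True)
class BudgetInputs:
    """Inputs of the release/oxidation budget.

    ``ch4_low/mean/high`` are the lowest, average and highest ice-bonded
    pore-water methane concentrations in mol m⁻³ pore water
    (1 µmol L⁻¹ = 10⁻³ mol m⁻³). ``f_ox_bounds`` is the (min, max) retained
    fraction oxidized.
    """

    degradation_rate_m_per_yr: float
    ch4_low_mol_m3: float
    ch4_mean_mol_m3: float
    ch4_high_mol_m3: float
    f_ox_bounds: tuple[float, float] = (0.0, 1.0)
    area_m2: float = PAN_ARCTIC_SUBMARINE_PERMAFROST_M2
    porewater_volume_fraction: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "degradation_rate_m_per_yr",
            "ch4_low_mol_m3",
            "ch4_mean_mol_m3",
            "ch4_high_mol_m3",
            "area_m2",
            "porewater_volume_fraction",
        ):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if not self.porewater_volume_fraction <= 1.0:
            raise ValidationError(
                f"porewater_volume_fraction must be <= 1, got "
                f"{self.porewater_volume_fraction!r}"
            )
        if not (
            self.ch4_low_mol_m3 <= self.ch4_mean_mol_m3 <= self.ch4_high_mol_m3
        ):
            raise ValidationError("require ch4 low <= mean <= high")
        f_min, f_max = self.f_ox_bounds
        if not (0.0 <= f_min <= f_max <= 1.0):
            raise ParameterError(
                f"f_ox_bounds must satisfy 0 <= min <= max <= 1, got "
                f"{self.f_ox_bounds!r}"
            )

    def concentration(self, level: str) -> float:
        if level not in _LEVELS:
            raise ParameterError(f"level must be one of {_LEVELS}, got {level!r}")
        return {
            "low": self.ch4_low_mol_m3,
            "mean": self.ch4_mean_mol_m3,
            "high": self.ch4_high_mol_m3,
        }[level]


@dataclass(frozen=True)
class BudgetResult:
    """One cell of the (concentration level × f_ox bound) budget grid."""

    ch4_release_mol_per_yr: float
    oxidized_carbon_tg_per_yr: float
    concentration_level: str
    f_ox_bound: str
    f_ox: float


def methane_release_rate(inputs: BudgetInputs, level: str = "mean") -> float:
    """Methane release rate (mol CH₄ yr⁻¹) at one concentration level.

    Independent of ``f_ox_bounds``: release precedes oxidation.
    """
    return (
        inputs.degradation_rate_m_per_yr
        * inputs.area_m2
        * inputs.porewater_volume_fraction
        * inputs.concentration(level)
    )


def oxidized_carbon(release_mol_per_yr: float, f_ox: float) -> float:
    """Oxidized carbon (Tg C yr⁻¹) for a given release and fraction oxidized."""
    if not (0.0 <= f_ox <= 1.0):
        raise ParameterError(f"f_ox must lie in [0, 1], got {f_ox!r}")
    if release_mol_per_yr < 0.0:
        raise ValidationError(
            f"release must be non-negative, got {release_mol_per_yr!r}"
        )
    return release_mol_per_yr * f_ox * CARBON_MOLAR_MASS_G_PER_MOL / 1.0e12


def budget_grid(inputs: BudgetInputs) -> list[BudgetResult]:
    """Full 3 × 2 grid: concentration level × retained-f_ox bound.

    Cells appear in the fixed order (low, mean, high) × (min, max).
    """
    f_by_bound = dict(zip(_BOUNDS, inputs.f_ox_bounds))
    grid = []
    for level in _LEVELS:
        release = methane_release_rate(inputs, level)
        for bound in _BOUNDS:
            f_ox = f_by_bound[bound]
            grid.append(
                BudgetResult(
                    ch4_release_mol_per_yr=release,
                    oxidized_carbon_tg_per_yr=oxidized_carbon(release, f_ox),
                    concentration_level=level,
                    f_ox_bound=bound,
                    f_ox=f_ox,
                )
            )
    return grid


def grid_extremes(grid: Iterable[BudgetResult]) -> tuple[float, float]:
    """Overall (min, max) oxidized carbon over the grid, Tg C yr⁻¹."""
    vals = [cell.oxidized_carbon_tg_per_yr for cell in grid]
    if not vals:
        raise ParameterError("budget grid is empty")
    return (min(vals), max(vals))


def budget_inputs_from_yaml(path: str | Path) -> BudgetInputs:
    """Load :class:`BudgetInputs` from a YAML mapping of its field names."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ParameterError(f"budget YAML {path} must hold a mapping")
    if "f_ox_bounds" in raw:
        raw["f_ox_bounds"] = tuple(raw["f_ox_bounds"])
    try:
        return BudgetInputs(**raw)
    except TypeError as exc:
        raise ParameterError(f"bad budget YAML field: {exc}") from exc
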