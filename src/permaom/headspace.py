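"""Dissolved methane from headspace gas-chromatography measurements.

Frozen sediment (a few grams) is immersed in a crimp-sealed serum vial
containing saturated NaCl brine; after equilibration, the methane mole
fraction of the headspace is measured by GC. The total methane in the vial
is the ideal-gas headspace inventory plus the brine-dissolved inventory via
the Bunsen solubility coefficient::

    n_total = x·P·V_hs / (R·T)  +  β·V_brine·(x·P/P₀) / V_m,STP

with x the headspace CH₄ mole fraction, P the vial pressure, V_hs the
headspace volume, β the Bunsen coefficient (volume of gas at STP dissolved
per volume of liquid per atmosphere of CH₄ partial pressure), and
V_m,STP = 22.414 L mol⁻¹. Saturated brine salts methane out, so β is small
(default 0.002) — but always explicit and echoed.

Concentrations are reported per litre of sediment pore water (whether
originally present as ice or water): the pore-water volume is
``sediment_mass_wet × water_content / ρ_w`` with ρ_w = 1.0 g mL⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import GeometryError, UndefinedBasisError, ValidationError

__all__ = [
    "HeadspaceSample",
    "dissolved_ch4_concentration",
    "headspace_volume_ml",
    "batch_dissolved_ch4",
    "R_J_PER_MOL_K",
    "VM_STP_L_PER_MOL",
    "P0_KPA",
    "DEFAULT_BUNSEN_BRINE",
]

R_J_PER_MOL_K = 8.314          # ideal gas constant
VM_STP_L_PER_MOL = 22.414      # molar volume of an ideal gas at STP
P0_KPA = 101.325               # standard atmosphere in kPa
#: Default Bunsen coefficient for CH₄ in saturated NaCl brine (salting-out
#: makes solubility nearly negligible); user-overridable per sample.
DEFAULT_BUNSEN_BRINE = 0.002


@dataclass(frozen=True)
class HeadspaceSample:
    """One sealed-vial headspace equilibration measurement."""

    vial_volume_ml: float
    brine_volume_ml: float
    sediment_mass_wet_g: float
    water_content: float          # mass fraction of wet sediment, [0, 1)
    ch4_mole_fraction: float      # headspace, dimensionless
    pressure_kpa: float
    temperature_k: float
    bunsen_coefficient: float = DEFAULT_BUNSEN_BRINE

    def __post_init__(self) -> None:
        for name in ("vial_volume_ml", "brine_volume_ml", "sediment_mass_wet_g",
                     "pressure_kpa", "temperature_k"):
            if not getattr(self, name) > 0.0:
                raise ValidationError(
                    f"{name} must be positive, got {getattr(self, name)!r}"
                )
        if not (0.0 <= self.water_content < 1.0):
            raise ValidationError(
                f"water_content must lie in [0, 1), got {self.water_content!r}"
            )
        if not (0.0 <= self.ch4_mole_fraction <= 1.0):
            raise ValidationError(
                f"ch4_mole_fraction must lie in [0, 1], got "
                f"{self.ch4_mole_fraction!r}"
            )
        if self.bunsen_coefficient < 0.0:
            raise ValidationError(
                f"bunsen_coefficient must be >= 0, got {self.bunsen_coefficient!r}"
            )


def headspace_volume_ml(
    sample: HeadspaceSample, sediment_density_g_per_ml: float = 2.0
) -> float:
    """Headspace volume: vial minus brine minus sediment (mL)."""
    v_sed = sample.sediment_mass_wet_g / sediment_density_g_per_ml
    v_hs = sample.vial_volume_ml - sample.brine_volume_ml - v_sed
    if not v_hs > 0.0:
        raise GeometryError(
            f"non-positive headspace volume ({v_hs:.3g} mL): vial "
            f"{sample.vial_volume_ml} mL, brine {sample.brine_volume_ml} mL, "
            f"sediment {v_sed:.3g} mL"
        )
    return v_hs


def dissolved_ch4_concentration(
    sample: HeadspaceSample, sediment_density_g_per_ml: float = 2.0
) -> float:
    """Pore-water methane concentration (µmol CH₄ per L pore water).

    Total vial methane (headspace ideal-gas moles plus brine-dissolved
    moles via the Bunsen coefficient) divided by the sample's pore-water
    volume. The two inventories are additive, so β = 0 reproduces the pure
    ideal-gas partition.

    Raises
    ------
    UndefinedBasisError
        ``water_content`` is zero — the pore-water basis is undefined.
    GeometryError
        Vial geometry leaves no headspace.
    """
    porewater_ml = sample.sediment_mass_wet_g * sample.water_content / 1.0
    if not porewater_ml > 0.0:
        raise UndefinedBasisError(
            "pore-water volume is zero (water_content == 0); the per-litre "
            "pore water basis is undefined"
        )
    v_hs_m3 = headspace_volume_ml(sample, sediment_density_g_per_ml) * 1.0e-6
    p_pa = sample.pressure_kpa * 1.0e3

    n_headspace = (
        sample.ch4_mole_fraction * p_pa * v_hs_m3
        / (R_J_PER_MOL_K * sample.temperature_k)
    )
    p_ch4_atm = sample.ch4_mole_fraction * sample.pressure_kpa / P0_KPA
    # β·V_brine·p gives mL of gas at STP; 22414 mL STP per mole
    n_dissolved = (
        sample.bunsen_coefficient * sample.brine_volume_ml * p_ch4_atm
        / (VM_STP_L_PER_MOL * 1.0e3)
    )
    total_umol = (n_headspace + n_dissolved) * 1.0e6
    porewater_l = porewater_ml * 1.0e-3
    return total_umol / porewater_l


def batch_dissolved_ch4(
    in_path: str | Path,
    out_path: str | Path | None = None,
    sediment_density_g_per_ml: float = 2.0,
) -> pd.DataFrame:
    """Process a CSV of headspace samples (one per row, field names as columns).

    Returns the input table with a ``ch4_uM_porewater`` column and a
    parameter echo; optionally writes it to ``out_path``.
    """
    table = pd.read_csv(in_path)
    results = []
    for _, row in table.iterrows():
        kwargs = {k: row[k] for k in (
            "vial_volume_ml", "brine_volume_ml", "sediment_mass_wet_g",
            "water_content", "ch4_mole_fraction", "pressure_kpa",
            "temperature_k",
        )}
        if "bunsen_coefficient" in table.columns and pd.notna(
            row.get("bunsen_coefficient")
        ):
            kwargs["bunsen_coefficient"] = row["bunsen_coefficient"]
        sample = HeadspaceSample(**kwargs)
        results.append(
            dissolved_ch4_concentration(sample, sediment_density_g_per_ml)
        )
    out = table.copy()
    out["ch4_uM_porewater"] = results
    out["sediment_density_g_per_ml"] = sediment_density_g_per_ml
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
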