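"""Dissolved methane from a vial headspace measurement.

A few grams of frozen sediment are immersed in saturated NaCl brine in a
sealed 20 mL serum vial; gas chromatography gives the headspace CH₄ mole
fraction. The calculator sums the ideal-gas headspace inventory and the
brine-dissolved inventory (Bunsen coefficient) and reports the result per
litre of sediment pore water.
"""

import dataclasses

from permaom import HeadspaceSample, dissolved_ch4_concentration

sample = HeadspaceSample(
    vial_volume_ml=20.0,
    brine_volume_ml=8.0,
    sediment_mass_wet_g=4.0,
    water_content=0.25,          # 1 g (=1 mL) pore water in the sample
    ch4_mole_fraction=0.01,      # 1% CH4 in the headspace
    pressure_kpa=101.325,
    temperature_k=298.15,
    bunsen_coefficient=0.002,    # CH4 in saturated brine: salted out
)

c = dissolved_ch4_concentration(sample)
print(f"pore-water methane: {c:.1f} uM")

no_brine_term = dataclasses.replace(sample, bunsen_coefficient=0.0)
print(f"headspace-only contribution: {dissolved_ch4_concentration(no_brine_term):.1f} uM")
print("The brine term is tiny by design: saturated NaCl pushes nearly all "
      "methane into the headspace, which is why the method works.")
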