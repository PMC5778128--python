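"""GDGT biomarker indices for a sulfate–methane transition zone sample.

The BIT index separates terrestrial (branched GDGT) from marine
(crenarchaeol) organic-matter sources; the methane index rises toward 1
where methane-cycling archaea dominate the isoprenoid tetraether pool, as
in an active AOM zone.
"""

from permaom import (
    GdgtMeasurement,
    archaeal_bacterial_ratio,
    bit_index,
    methane_index,
)

smtz_sample = GdgtMeasurement(
    br_I=120.0, br_II=80.0, br_III=40.0,   # branched, terrestrial bacteria
    gdgt_1=30.0, gdgt_2=22.0, gdgt_3=10.0, # isoprenoid, methane cycling
    crenarchaeol=1.5, cren_isomer=0.4,     # marine Thaumarchaeota marker
    archaeal_ether_sum=95.0,
    bacterial_ether_sum=30.0,
)

print(f"BIT index:     {bit_index(smtz_sample):.3f}  (~1 -> terrestrial organic matter)")
print(f"methane index: {methane_index(smtz_sample):.3f}  (~1 -> AOM-dominated archaea)")
print(f"archaeal:bacterial ether lipids: {archaeal_bacterial_ratio(smtz_sample):.2f}")
print("High BIT with a high methane index is the signature expected at a "
      "permafrost-table SMTZ: terrestrial sediment hosting an active "
      "methane-cycling archaeal community.")
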