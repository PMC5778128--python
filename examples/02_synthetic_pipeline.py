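"""Full pipeline on a synthetic core with known ground truth.

Generates a methane-rich core emulating a recently inundated site (sharp
sulfate–methane transition zone at the permafrost table, frozen-section
methane ~8× a long-inundated background), then runs zonation, isotope-shift
extraction, scenario evaluation and SMTZ detection, and compares the
estimates with the generator's truth record.
"""

from permaom import analyze_profile, detect_smtz, generate_core
from permaom.pipeline import estimate_fraction_oxidized
from permaom.synthetic import bk2_like

params = bk2_like(seed=42)
profile, truth = generate_core(params)
print(f"core {profile.core_id}: {len(profile)} horizons, "
      f"depths {profile.depth_range[0]:.1f}-{profile.depth_range[1]:.1f} mbsf")
print(f"truth: f_ox={truth.f_ox_true}, delta_p={truth.delta_p_true} permil, "
      f"SMTZ {truth.smtz_interval} mbsf, scenario {truth.scenario_name}")

report = analyze_profile(profile)
s = report.shift
print(f"max shift: {s.shift:.2f} permil ({s.delta_o:.2f} at {s.depth_o:.1f} mbsf "
      f"over {s.delta_p:.2f} at {s.depth_p:.1f} mbsf)")

f_mean = estimate_fraction_oxidized(profile, params.scenario_true, estimator="mean")
print(f"zone-mean estimate of f_ox under the true scenario: {f_mean:.3f} "
      f"(truth {truth.f_ox_true})")

smtz = detect_smtz(profile)
print(f"detected SMTZ: {smtz.top_mbsf:.2f}-{smtz.bottom_mbsf:.2f} mbsf "
      f"(true midpoint {sum(truth.smtz_interval)/2:.2f} mbsf)")
print("The zone-mean estimator recovers the simulated oxidation fraction; "
      "the max-pair statistic in the report is deliberately the published, "
      "more conservative extreme-value reading.")
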