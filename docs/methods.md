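# Methods

## The problem

Submarine permafrost on Arctic shelves holds methane in its ice-bonded pore
space. As warm, saline seawater degrades the permafrost from the top, that
methane is released into the overlying thawed sediment, where anaerobic
methanotrophic communities can consume it before it reaches the water
column. `permaom` quantifies this microbial methane filter from pore-water
geochemistry alone: depth profiles of methane concentration, its carbon
stable-isotope signature (δ¹³C-CH₄, ‰ VPDB), sulfate, and the electron
acceptors nitrate, manganese and iron.

## Isotope zonation

Anaerobic oxidation of methane (AOM) preferentially consumes ¹²CH₄ and
leaves the residual methane enriched in ¹³C. Horizons are therefore
classified by two thresholds on δ¹³C-CH₄:

* **oxidized**: δ¹³C > −37‰ (strict),
* **source** (produced or trapped methane): δ¹³C < −52‰ (strict),
* **intermediate** between the two, **unconstrained** when unmeasured.

Both thresholds are configuration defaults, overridable per run. The
mass-balance input is the contrast between an oxidized layer and a source
layer lying *below* it (δ_p is required subjacent to δ_o, because methane
diffuses upward out of its source into the oxidation zone).

Two contrast statistics are implemented:

* `max_isotope_shift` — the largest δ_o − δ_p over all qualifying pairs.
  This is the statistic a geochemist reads off a profile ("the highest
  change in isotope signature"). Ties are broken toward the smallest depth
  separation, then the shallowest oxidized horizon — the most local, least
  transport-confounded pair.
* `mean_isotope_shift` — the zone-mean contrast (mean oxidized δ minus mean
  source δ, carried at the mean depth of each zone).

The distinction matters under measurement noise. The max-pair statistic is
an extreme-value statistic: with iid Gaussian noise of standard deviation σ
on each of *n* horizons per zone, its expectation is inflated by roughly
2·σ·E[max of n standard normals] ≈ 2σ√(2 ln n) — at σ = 1‰ and n ≈ 40 that
is ≈ +3.5‰, i.e. ≈ +0.1 on the fraction oxidized under a 38‰-per-unit-f
scenario. The zone-mean contrast is unbiased under the same noise model.
Reports therefore carry the max-pair shift (the published reading), while
parameter-recovery validation on synthetic cores uses the zone-mean
estimator (`estimate_fraction_oxidized(..., estimator="mean")`).

## Fraction of methane oxidized

For open-system, diffusion-transported methane, the fraction oxidized is

    f_ox = (δ_o − δ_p) / (1000 · (α_ox − α_trans))

with α_ox the kinetic fractionation factor of oxidation and α_trans that of
transport. The registry carries six literature α_ox values — marine
sulfate-AOM bounds 1.009 and 1.039, freshwater sulfate-AOM 1.030, iron-AOM
1.031, nitrate-AOM 1.032, and AOM by extracellular electron transfer (e.g.
to humic acids) 1.0174 — all against the soil diffusive transport factor
α_trans = 1.001. The registry is YAML-serializable so users can add
literature values without code changes.

A scenario whose implied f_ox falls outside [0, cap] (cap defaults to 1)
cannot describe the observed shift and is flagged **not retained**; negative
fractions (δ_o below δ_p) are likewise flagged rather than raised, so
degraded data still flows to the report. Reported ranges (and the budget's
f_ox bounds) are the min/max capped fraction over retained scenarios.

## Methane release and oxidized-carbon budget

Top-down degradation at rate v (m yr⁻¹) of permafrost with pore-water
volume fraction φ and pore-water methane concentration c (mol m⁻³) over
area A (m²) releases R = v·A·φ·c mol CH₄ yr⁻¹; the oxidized-carbon budget is
B = R·f_ox·12.011 g mol⁻¹ / 10¹² g Tg⁻¹ (Tg C yr⁻¹, carbon in CH₄). The
grid evaluates all six (concentration level low/mean/high) × (f_ox bound
min/max) combinations plus overall extremes.

Defaults: A = 3 × 10¹² m² (the estimated pan-Arctic submarine permafrost
area); v = 0.006 or 0.053 m yr⁻¹ (the two observed core degradation rates,
derived upstream from coastal erosion rate and permafrost-table depth — no
formula for v is reimplemented here). φ is deliberately an explicit,
always-echoed assumption (default 0.4): published pore-water concentrations
are per pore-water volume, and the sediment water content used for
upscaling dominates the absolute budget. Because φ and the per-sample
concentration levels behind any published budget are generally not
recoverable from a paper's figures, absolute Tg values from this module are
conditional on φ by construction; the module surfaces the parameter instead
of burying it.

## Headspace calculator

Dissolved methane is measured by immersing a few grams of frozen sediment
in saturated NaCl brine in a sealed vial and measuring the headspace CH₄
mole fraction x by GC. The standard equilibration formulation is used:

    n_total = x·P·V_hs/(R·T) + β·V_brine·(x·P/P₀)/V_m,STP

ideal-gas headspace moles plus Bunsen-solubility dissolved moles
(R = 8.314 J mol⁻¹ K⁻¹, V_m,STP = 22.414 L mol⁻¹, P₀ = 101.325 kPa).
β defaults to 0.002 (saturated brine salts methane out almost completely);
it is a documented default, not an asserted literature constant, and is
echoed in outputs. Concentrations are reported per litre of sediment pore
water (mass_wet × water_content at ρ_w = 1.0 g mL⁻¹, configurable),
regardless of whether that water was originally ice. Sediment volume uses a
wet density of 2.0 g mL⁻¹ by default. No non-ideal-gas or
temperature-dependent-solubility corrections are applied.

## GDGT biomarker indices

BIT = (brGDGT-I+II+III) / (brGDGT-I+II+III + crenarchaeol);
MI = (GDGT-1+2+3) / (GDGT-1+2+3 + crenarchaeol + crenarchaeol isomer);
plus the plain archaeal:bacterial ether-lipid quotient. All are
scale-invariant in the raw response units; zero denominators raise a
dedicated error. Which compounds enter the archaeal/bacterial ether sums is
left to the caller, since that assignment is laboratory-specific.

## Synthetic cores and what they do (not) show

The generator is the exact algebraic inverse of the mass balance: it fixes
a true fraction oxidized f_ox and source signature δ_p, places the oxidized
zone's expected signature at δ_o = δ_p + 1000·(α_ox − α_trans)·f_ox, and
builds qualitative profile shapes around that skeleton — logistic sulfate
decline across the SMTZ, methane suppressed above the SMTZ (2% of
background) and high below it, an optional Gaussian methane peak (one
horizon is placed exactly at the peak depth so the noiseless maximum equals
the configured peak), ice-bonded flags over a configured interval. δ noise
is additive Gaussian (default 0.5‰, the replicate precision of routine
IRMS); concentration noise is multiplicative log-normal (default 5%
relative), keeping concentrations positive. One numpy `default_rng` stream
per core, fully determined by the integer seed, which is recorded in the
truth record.

Two presets emulate the qualitative structure of the two reference cores:

* `c2_like` — 118 horizons over 0.5–71 mbsf, background CH₄ 48 µM with a
  990 µM peak at 52 mbsf, sulfate 18 mM declining to 0.2 mM across an SMTZ
  at 38–44 mbsf inside the ice-bonded section (34.3–58.7 mbsf), degradation
  0.006 m yr⁻¹; truth f_ox = 0.9 under the freshwater sulfate-AOM factor
  (δ_p = −63‰ → δ_o ≈ −36.9‰, shift ≈ 26.1‰). Under the default registry
  the noiseless pipeline retains exactly the four strong-fractionation
  scenarios (α_ox 1.030–1.039) and rejects the low-marine and
  electron-transfer factors, mirroring the field situation the presets are
  meant to exercise.
* `bk2_like` — 80 horizons over 0.5–47.7 mbsf, frozen-section CH₄ 384 µM
  (8× the c2 background), sharp SMTZ at the permafrost table
  (24.0–24.7 mbsf), sulfate 7 mM above vs 0.08 mM inside the frozen
  section, degradation 0.053 m yr⁻¹; truth f_ox = 0.76 under the
  high-marine sulfate-AOM factor (δ_p = −64‰ → δ_o ≈ −35.1‰).

The truth record also carries a budget computed from the generated
ice-bonded methane inventory at f_ox_true, so the budget path can be
validated end-to-end to 1e-12 relative on noiseless cores.

These fixtures emulate the *shape* of real profiles, nothing more. Real
cores have irregular sampling, multi-modal δ structure, partially thawed
interbeds, and δ measurable only in parts of the core; passing tests on
synthetic cores demonstrate the correctness and statistical calibration of
the estimators under the stated noise model, not their performance on any
specific field dataset. In particular the published per-core oxidized
fractions and Tg budgets depend on unpublished per-sample δ pairs,
concentrations and water contents and are deliberately not reproduction
targets: the pipeline reports whatever the supplied profile yields.

## SMTZ detection

Field SMTZs are identified by inspection; the detector is a reproducible
stand-in. Both analytes are linearly interpolated between measured depths
and normalized to their own profile maximum; the detector returns the
adjacent measured depths bracketing the first sign change of
(sulfate_norm − methane_norm) across which sulfate strictly decreases,
methane strictly increases, and sulfate at the interval top is at least
`sulfate_floor` (default 1 mM). Fewer than three co-measured horizons is an
error; no crossing is `None`, not an error. Known limitation: with a strong
deep methane peak (as in `c2_like`) the max-normalization compresses the
methane curve near the SMTZ and shifts the detected crossing below the
sulfate-decline midpoint; on sharp transition zones without a dominating
peak (`bk2_like`) the detected interval brackets the true midpoint
essentially always (validated at ≥95% over 200 noisy replicates).

## Numerical and interface choices

* Profile CSV: single canonical dialect
  (`depth_mbsf,ch4_uM,d13c_ch4_permil,so4_mM,no3_uM,mn_uM,fe_uM,state`),
  empty string = missing, floats written as shortest round-tripping
  representation and parsed with round-trip precision, so write∘read is the
  identity bit-for-bit. Duplicate depths are rejected, never averaged.
* δ¹³C values are validated to [−120, +20]‰ VPDB; concentrations to ≥ 0.
* Thresholds are strict inequalities; a horizon exactly at a threshold is
  intermediate.
* `fraction_oxidized` raises only for α_ox = α_trans (the model divides by
  their difference); all other degenerate outcomes are flags.
* Config validation collects all violations and reports them together, so
  batch runs fail with a complete diagnosis rather than one error at a
  time. Reports echo every assumption (thresholds, cap, pore-water
  fraction, Bunsen default) and the package version.
* Year-based rates use calendar years as supplied; no day-level conversion
  arises in the implemented paths.

## Validation problem sizes

Property tests run the generator at its preset sizes (80–118 horizons);
the stochastic recovery check uses 200 seeded `bk2_like` replicates with
1‰ δ-noise, chosen to pin the mean estimate to ±0.005 (2 s.e.) against the
0.02 acceptance band. The whole suite completes in about a second.
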