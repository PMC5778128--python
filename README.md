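# permaom

Quantifying the microbial methane filter in thawing submarine permafrost
from pore-water geochemistry.

Arctic shelf sediments hold permafrost that has been degrading since it was
flooded by the sea. As the ice-bonded section thaws from the top, the
methane in its pore space is released upward — unless anaerobic
methanotrophic communities oxidize it first. Because anaerobic oxidation of
methane (AOM) enriches the residual CH₄ in ¹³C, the δ¹³C-CH₄ contrast
between an oxidized layer and the source layer below it records how much
methane was consumed. `permaom` implements that quantification chain for
biogeochemists working with depth-resolved pore-water profiles:

* **profiles** — a validated core-profile container with a canonical CSV
  dialect (depth in mbsf; CH₄ in µM pore water; δ¹³C-CH₄ in ‰ VPDB;
  sulfate, nitrate, Mn, Fe; frozen-state flags), round-tripping bit-exactly.
* **zonation** — oxidized (δ¹³C > −37‰) / source (δ¹³C < −52‰)
  classification, isotope-shift extraction (extreme-pair and zone-mean
  statistics), and sulfate–methane transition zone (SMTZ) detection from
  opposing normalized gradients.
* **fractionation** — the open-system isotope mass balance

      f_ox = (δ_o − δ_p) / (1000 · (α_ox − α_trans))

  evaluated against a six-scenario registry of literature fractionation
  factors (marine sulfate-AOM bounds 1.009/1.039, freshwater sulfate-AOM
  1.030, Fe-AOM 1.031, N-AOM 1.032, electron-transfer AOM 1.0174; diffusive
  transport α_trans = 1.001), with automatic rejection of scenarios whose
  implied fraction exceeds 1.
* **budget** — methane release from top-down permafrost degradation
  (release = rate × area × pore-water fraction × concentration) upscaled to
  the ~3 million km² of pan-Arctic submarine permafrost, and the oxidized
  carbon in Tg C yr⁻¹.
* **headspace** — dissolved CH₄ per litre pore water from brine-immersed
  vial headspace GC measurements (ideal gas + Bunsen solubility).
* **lipids** — GDGT biomarker indices: BIT, methane index, archaeal:
  bacterial ether-lipid ratio.
* **synthetic** — seeded synthetic cores with known ground truth (the
  exact forward model of the mass balance), so every stage is testable
  without field data.
* **pipeline / CLI** — one configured run from profile CSV to a JSON report
  in which every number is traceable and every assumption echoed.

## Worked example

The largest observed contrast in a long-inundated core is an oxidized layer
at −37‰ above a source layer at −72‰ — a 35‰ shift:

```python
from permaom import IsotopeShift, evaluate_scenarios

shift = IsotopeShift(delta_o=-37.0, delta_p=-72.0, depth_o=50.0, depth_p=52.0)
for e in evaluate_scenarios(shift):
    print(f"{e.scenario.name:18s} alpha_ox={e.scenario.alpha_ox:<7} "
          f"f_raw={e.f_raw:7.4f}  {'retained' if e.retained else 'REJECTED'}")
```

```
S-AOM-marine-low   alpha_ox=1.009   f_raw= 4.3750  REJECTED
S-AOM-marine-high  alpha_ox=1.039   f_raw= 0.9211  retained
S-AOM-freshwater   alpha_ox=1.03    f_raw= 1.2069  REJECTED
Fe-AOM             alpha_ox=1.031   f_raw= 1.1667  REJECTED
N-AOM              alpha_ox=1.032   f_raw= 1.1290  REJECTED
EEL-AOM            alpha_ox=1.0174  f_raw= 2.1341  REJECTED
```

A 35‰ shift divided by 1000·(α_ox − α_trans) exceeds 1 for every weak
fractionation factor: only the strongest marine sulfate-AOM factor can
explain it (92% of the methane oxidized). Scenarios implying f_ox > 1 are
physically impossible for the given shift and are dropped from reported
ranges.

The same chain runs end-to-end on a synthetic core with known truth
(`examples/02_synthetic_pipeline.py`):

```
core bk2_like-seed42: 80 horizons, depths 0.5-47.7 mbsf
truth: f_ox=0.76, delta_p=-64.0 permil, SMTZ (24.0, 24.7) mbsf, scenario S-AOM-marine-high
max shift: 31.02 permil (-34.06 at 1.7 mbsf over -65.07 at 45.9 mbsf)
zone-mean estimate of f_ox under the true scenario: 0.763 (truth 0.76)
detected SMTZ: 23.80-24.40 mbsf (true midpoint 24.35 mbsf)
```

The zone-mean estimator recovers the simulated oxidation fraction to within
a few thousandths, and the SMTZ detector brackets the true transition.
`examples/` contains one short script per capability (mass balance, full
pipeline, budget grid, headspace calculator, lipid indices); each prints
the numbers it computes and a line on what they mean. A thin CLI wraps the
same entry points:

```bash
permaom simulate --preset bk2_like --seed 3 --out out/
permaom analyze --profile out/bk2_like-seed3.csv
permaom budget --config budget.yaml
```

## Scope notes

Sequence analysis (16S rRNA/mcrA amplicons), qPCR calibration, CARD-FISH
imaging and lipid extraction chemistry are out of scope: the package starts
from measured geochemistry. Absolute Tg C yr⁻¹ budgets are conditional on
the pore-water volume fraction used for upscaling, which is an explicit,
echoed parameter — see `docs/methods.md` for the model, assumptions,
defaults and known limitations.
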