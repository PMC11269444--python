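# aquabudget

Feed-evaluation analytics for tank-replicated fish feeding trials:
marker-based nutrient digestibility, dry-matter nutrient mass-balance
budgets, and per-kg-fish environmental-impact conversion ratios, with
the ANOVA / Tukey–Kramer comparison layer used to annotate such trials.

The package grew out of the question of replacing fishmeal in
salmonid aquafeeds with defatted microalgal co-product
(*Nannochloropsis* sp.): does the substitution hold growth and
phosphorus digestibility while lowering nutrient loading and
life-cycle impacts? Answering that requires four linked computations,
all implemented here:

- **Apparent digestibility coefficient (ADC).** With an indigestible
  marker (yttrium oxide at 1.0 % of the diet), the nutrient:marker
  ratio shift between diet and feces gives

  `ADC = 100 × [1 − (N_feces/N_diet) × (M_diet/M_feces)]`,

  and digestible content = total content × ADC/100.

- **Nutrient budget** (g per kg dry-weight gain): intake, retained,
  solid (undigested), rejected = intake − retained, dissolved =
  rejected − solid. The budget closes exactly by construction.
  `FCR = feed intake / weight gain`.

- **Environmental-impact conversion ratio (EICR)** over six
  categories (GWP, water, land, MEP, FEP, BRU):
  `EICR_{i,k} = Σ_j CF_j · EI_{j,k} · FCR_i` — inclusion-weighted
  per-kg ingredient impacts times the feed conversion ratio. Real
  inventories must be supplied by the user (CSV); a clearly-labelled
  synthetic demo inventory exists for tests and examples.

- **Group comparisons.** One-way ANOVA and Tukey–Kramer pairwise
  tests (unbalanced-n aware) with a compact letter display (groups
  sharing a letter are not significantly different).

A synthetic feeding-trial generator (4 diets × 4 tanks × 30 fish,
64 days, configurable truth, single-seed reproducible) makes the whole
pipeline testable end-to-end with known ground truth, including the
four built-in trial formulations (Reference, 33N, 66N, 100N — 0 / 33 /
66 / 100 % fishmeal replacement).

## Worked example

```python
import aquabudget as aq

# Digestibility from a diet/feces assay pair (percent of dry matter)
diet  = aq.CompositionSample("diet",  "P", nutrient_pct=1.82, marker_pct=1.0)
feces = aq.CompositionSample("feces", "P", nutrient_pct=1.30, marker_pct=2.0, tank_id="T01")
print("ADC of P:", round(aq.adc(diet, feces), 2), "%")
print("digestible P:", aq.digestible_content(18.2, 73), "g/kg feed")

# A synthetic trial with known truth, analysed end-to-end
trial = aq.generate_trial(aq.TrialConfig(seed=7, fcr_cv=0.03))
res = aq.analyze_trial(trial)
for d in ("Reference", "33N", "66N", "100N"):
    r = res["adc"][(d, "P")]
    print(f"{d:>9}: pooled P ADC {r.adc_pct:5.2f} +/- {r.se:.2f} % (n={r.n_tanks})")

inv = aq.synthetic_demo_inventory()   # fabricated demo numbers, not LCI data
for r in aq.replacement_sweep(aq.trial_diets(), inv, res["fcr_asfed"], ["BRU"]):
    print(f"BRU EICR {r.diet_id:>9}: {r.value:.3f} +/- {r.se:.3f} {r.units}")
```

prints

```
ADC of P: 64.29 %
digestible P: 13.29 g/kg feed
Reference: pooled P ADC 73.43 +/- 0.59 % (n=4)
      33N: pooled P ADC 70.45 +/- 1.00 % (n=4)
      66N: pooled P ADC 70.95 +/- 0.88 % (n=4)
     100N: pooled P ADC 71.82 +/- 0.48 % (n=4)
BRU EICR Reference: 1.769 +/- 0.032 kg C/kg fish
BRU EICR       33N: 1.481 +/- 0.013 kg C/kg fish
BRU EICR       66N: 1.014 +/- 0.016 kg C/kg fish
BRU EICR      100N: 0.553 +/- 0.009 kg C/kg fish
```

The ADC line is the marker-ratio estimate for one tank: 1.30/1.82 of
the nutrient against twice the marker concentration means ~64 % of the
P disappeared in transit. The pooled ADCs recover the generator's
configured truths (73 / 70 / 71 / 71 %) within sampling noise at 5 %
measurement CV. The biotic-resource-use conversion ratio falls
strictly as fishmeal is replaced — the expected signature when only
fishmeal carries a biotic burden — while its standard error reflects
the per-tank FCR spread. Because the inventory is synthetic the
absolute EICR numbers are placeholders; supply your own inventory CSV
(`ingredient,category,value,units,source`) for real assessments.

Group comparison on any per-tank response:

```python
groups = [aq.GroupSample(d, values) for d, values in per_diet_values.items()]
cmp = aq.compare_groups(groups, alpha=0.05)
cmp.anova_F, cmp.anova_p, cmp.letters   # e.g. {'Ref': 'a', '33N': 'ab', ...}
```

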