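# Methods

## Scope and model

`aquabudget` implements the quantitative layer of a tank-replicated fish
feeding trial that evaluates a feed ingredient substitution — here the
serial replacement of fishmeal (FM) by defatted *Nannochloropsis* sp.
microalgal co-product in juvenile rainbow trout diets — on three linked
axes:

1. **Apparent digestibility.** With an indigestible marker (yttrium
   oxide, 1.0 % of the diet) mixed into the feed, the apparent
   digestibility coefficient of a nutrient is estimated from the
   nutrient:marker concentration shift between diet and feces:

   ADC = 100 × [1 − (N_feces / N_diet) × (M_diet / M_feces)],

   with N, M in percent of dry matter. The estimator is a pure ratio:
   any consistent rescaling of either analyte cancels, which is why no
   Y ↔ Y₂O₃ stoichiometric conversion is applied. Digestible nutrient
   content of a feed is total content × ADC/100.

2. **Nutrient mass balance.** Per tank and nutrient, on a dry-matter
   basis, in g per kg of dry-weight gain:

   - intake = dry feed per fish × diet % / 100
   - retained = final body nutrient mass − initial body nutrient mass
   - solid = intake × (1 − ADC/100)
   - rejected = intake − retained
   - dissolved = rejected − solid

   The last two are definitions, so the budget closes exactly:
   intake = retained + solid + dissolved. Feed conversion ratio
   FCR = feed intake / weight gain.

3. **Environmental-impact conversion ratios.** For diet *i* and impact
   category *k*: EICR_{i,k} = Σ_j CF_j · EI_{j,k} · FCR_i, where CF_j
   is ingredient *j*'s inclusion (kg per kg feed) and EI_{j,k} its
   life-cycle impact per kg. Six categories are carried with units:
   GWP (kg CO₂e), water (m³), land (m²), MEP (kg N), FEP (kg P), BRU
   (kg C). Negative EI values are legal (recycled process water).

Group comparison uses one-way ANOVA and Tukey–Kramer pairwise tests
with tanks as the experimental unit, plus a compact letter display.

## Conventions and documented equation choices

- Inclusions, replacement levels and digestibilities are stored as
  fractions internally; percent appears only at I/O boundaries. This
  prevents silent ×100 slips between the percent-based ADC arithmetic
  and the kg/kg impact arithmetic.
- The per-fish → per-kg-gain conversion multiplies by 1000 uniformly
  (g per kg of gain) for all budget components; a ×100 variant seen in
  some write-ups of the intake equation is dimensionally inconsistent
  and is not used.
- Retention is the *difference* of final and initial body nutrient
  mass. Typeset versions of this equation sometimes join the two terms
  with a product sign; mass balance requires subtraction, and that is
  what is implemented.
- ADC estimates from noisy assays can leave [0, 100]; they are
  returned unclipped (clipping would bias replicate means) and flagged
  with a warning. Pooling across tanks uses unclipped values.
- The marker is validated into (0, 100] on diet and feces samples; a
  zero marker or zero diet nutrient raises rather than returning an
  undefined ratio.
- The column-sum validation of a formulation ignores the marker (it is
  added on top of the basal mix) and accepts |Σ inclusions − 1| ≤ tol,
  default tol = 0.005 — the bundled trial formulations sum to
  99.95–100.25 % and the filler conventions behind that spread are not
  recoverable, so the tolerance is a package choice.

## Statistics

- ANOVA F is the classical between/within mean-square ratio; the
  all-values-identical degenerate case returns F = 0, p = 1 instead of
  0/0.
- Tukey–Kramer: q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)),
  referred to the studentized-range distribution with k groups and
  N − k degrees of freedom. The 1/n_i + 1/n_j term handles unbalanced
  replication (n = 4 tanks, or 3 where a tank yielded < 0.1 g feces).
  p-values use `scipy.stats.studentized_range`, accurate well below
  1e-6; the test suite cross-checks against `scipy.stats.tukey_hsd`
  and statsmodels' `pairwise_tukeyhsd`.
- Compact letters use insert-and-absorb followed by a redundancy
  prune; groups share a letter exactly when their adjusted p exceeds
  alpha. Minimality is verified exhaustively in the tests for up to 5
  groups.
- Significance is p ≤ alpha (alpha default 0.05). No normality or
  variance-homogeneity screening is performed.
- FCR spread across replicate tanks is the only uncertainty propagated
  into EICR standard errors; inventory (EI) uncertainty is out of
  scope.

## Synthetic trial generator

The generator emulates the trial design — 4 diets × 4 tanks × 30 fish,
64 days, initial live weight 40.46 ± 1.44 g (treated as the SD of tank
means), marker at 1.0 % — by *inverting* the analysis equations, so the
configured truth is recoverable by construction:

- **Growth** is linear at a per-diet daily live gain (defaults
  0.847 / 0.7898 / 0.8144 / 0.8086 g/day, the slopes of the trial's
  growth fits). The as-fed feed allowance is back-computed from the
  configured FCR, so a noise-free trial returns the configured FCR
  exactly.
- **Bases.** Configured FCR is as-fed feed per live-weight gain (the
  scale on which such trials report 0.93–1.01), while the budget runs
  on dry matter. Fixed dry-matter fractions convert between them: feed
  0.94, whole fish 0.28 (neither is reported by typical trials; both
  are configurable). The dry-basis FCR is then ≈ 0.93 × 0.94 / 0.28 ≈
  3.1, which makes the default budget internally consistent: reference
  P intake ≈ 57 g/kg dry gain, retention 22 (body P 2.2 % of dry
  mass), solid ≈ 15 at ADC 73 %. A literal dry-basis reading of an FCR
  near 1 would force retention to exceed digestible intake and the
  budget could not close with realistic body composition.
- **Feces composition** comes from mass balance: with nutrient
  digestibility a and dry-matter digestibility d (default 0.75), one
  kg of dry feed leaves (1 − d) kg of feces holding all the marker and
  a (1 − a) share of the nutrient, so the noise-free concentrations
  satisfy the ADC identity exactly.
- **Noise model.** Feces composition measurements get multiplicative
  mean-one lognormal noise with CV `measurement_cv` (default 0.05, a
  package choice — such trials publish no error model). The mean-one
  parameterization (exp N(−σ²/2, σ²)) keeps concentrations positive
  and the pooled ADC unbiased to first order. Tank-mean initial
  weights get additive normal noise. An optional `fcr_cv` (default 0)
  adds tank-level feeding variability so EICR uncertainty propagation
  can be exercised; it is off by default so that FCR recovery stays
  exact. All randomness flows from a single integer seed;
  regeneration is bit-identical.
- **Ground truth** records true ADC, FCR on both bases, and the full
  noise-free budget per diet × nutrient (evaluated at the mean initial
  weight; with stage-constant body composition the retained term is
  independent of the weights).

What passing tests on this generator show — and what they do not: the
generator reproduces the *design* and the estimators' input structure,
not fish biology. There are no tank random effects beyond i.i.d.
noise, no uneaten-feed correction, no nutrient leaching from feces
before collection, no growth curvature, and diet composition is
carried at its formulated value. Parameter-recovery results therefore
validate the estimation pipeline, not the husbandry assumptions.

## Impact inventories

Absolute conversion ratios depend on external life-cycle inventory
databases (Ecoinvent, Agri-footprint, primary literature) whose
per-ingredient values are licensed and not bundled. Real analyses must
supply an inventory CSV (`ingredient,category,value,units,source`).
`synthetic_demo_inventory()` ships fabricated placeholder numbers on
loosely plausible orders of magnitude so the pipeline is testable; its
name and docstring mark it synthetic, and nothing downstream treats it
as data. Qualitative structure is still meaningful: with the biotic
burden confined to fishmeal, the BRU conversion ratio must fall
strictly along the serial-replacement gradient, and the tests assert
exactly that.

## Problem sizes and numerical tolerances

The property suites run 1000 random draws for the budget-closure and
digestion-oracle checks (tolerance 1e-9, relative), 200 replicate
trials for the ADC bias check (< 0.5 percentage points), and 2000 null
simulations for the familywise-error calibration of the Tukey layer
(acceptance band [0.03, 0.07] at alpha 0.05), with 50 of those
simulations additionally driven through the full pairwise/letter path.
These sizes give stable verdicts at seeds fixed in the tests while
keeping the default suite fast. The 2000-simulation check compares
each simulation's maximum studentized-range statistic to the Tukey
critical value, which for balanced groups is algebraically the same
event as "any adjusted p ≤ alpha".

## Known limitations

- ADC pooling treats tanks as i.i.d.; shared diet-assay error is not
  modelled (diet composition is measured once per diet in practice).
- The live/dry conversion uses fixed scalar fractions; real dry-matter
  content varies with fish size and diet.
- The compact-letter prune is verified minimal only to 5 groups; for
  many-group designs letter counts may exceed the true minimum.
- Economic conversion ratios and growth-curve regression are out of
  scope.
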