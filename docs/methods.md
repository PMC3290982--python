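# Methods

## The scoring algorithm

An applicator's relative exposure intensity is

    score = (MIX + APPLY + REPAIR) × PPE

with weights looked up in a versioned table:

* **MIX** — mixing/loading frequency: did not mix / mixed <50% of the
  time / mixed >50% of the time, weighted 0/3/9 (v1) or 0/20/50 (v2).
* **APPLY** — one of 29 application methods. v1 weights span 1–9 with
  five methods unassigned (garden hose, squeeze bottle, watering can,
  hand/push spreader, planter box); v2 assigns all 29, spanning 10–150.
  Requesting a v1 score for an unassigned method raises an error rather
  than silently contributing zero — a zero weight would be a claim about
  exposure, not an absence of information.
* **REPAIR** — equipment repair yes/no, weighted 2/0 (v1) or 20/0 (v2).
* **PPE** — `1 − total reduction`. Chemically-resistant (CR) or rubber
  gloves reduce exposure 40% (v1) or 60% (v2). Other items: v1 grants
  30% if at least one of {cartridge respirator, Tyvek coveralls} is worn
  and 20% if at least one of {face shield, goggles, boots, apron, other};
  v2 grants 10% per distinct non-glove item, capped at 30%. v1 also
  grants 20% for fabric/leather gloves; v2 grants none (monitoring showed
  them non-protective). The total reduction is capped at 90%, so the
  multiplier lies in [0.10, 1.0].

Design choices where the published description leaves room:

* **Several reported methods.** The APPLY weight is the *maximum* over
  the reported methods (mixed boom+hand application days were analysed in
  the hand-spray group, i.e. assigned the higher-exposure method). A
  per-method score listing is exposed via `method_scores`.
* **Both glove types reported.** CR-glove rules apply and fabric gloves
  are ignored; anything else double-counts glove protection in v1.
* **v1 reduction combination.** The three v1 reduction classes add
  before the 90% cap. This is the only reading under which the printed
  v1 minimum score of 0.1 is achievable (0.40 + 0.30 + 0.20 = 0.90).
* **Category bounds.** With cutpoints (50, 100) the bins are `<50`,
  `[50, 100]`, `>100` — the closed middle bin follows the printed
  "50–100" label. With one cutpoint the boundary belongs to the upper
  group (`<50` / `≥50`).
* **Score ranges.** `score_range` enumerates the full cross-product of
  mix level × assigned method × repair × every subset of the nine PPE
  items; v2 spans 1–220 and v1 spans 0.1–20.

PPE multipliers are rounded at the 12th decimal so that sums of decimal
reduction fractions (e.g. 0.6 + 0.3) hit the cap exactly; scores are
otherwise exact floating-point arithmetic and deterministic.

## The concentration model

The evaluation regresses post-application urinary biomarker
concentration Y (µg/L) on the algorithm's component variables with the
same additive-times-multiplicative structure as the score:

    Y = (α₀ + α₁·Mix + α₂·Method + α₃·Repair) × (1 − β₁·Gloves − β₂·PPEother)

All covariates are 0/1; `Method` codes the higher-exposure method of the
pair under study (hand spray = 1 vs boom = 0 for a 2,4-D-style design;
boom = 1 vs in-furrow = 0 for a chlorpyrifos-style design) via the
`method_coded_one` label set. α₀ is the referent-cell concentration; β₁
and β₂ are fractional reductions.

**Fitting** (`Eq1Regressor`, `fit_eq1`) is least squares on the raw µg/L
scale — homoscedastic residuals, exactly as the model is written — even
though the generator produces lognormal data. This deliberate
model/generator mismatch mirrors how such calibration fits are done in
practice; the fitted coefficients are used to rank scenarios, not to
model the error law. Numerics:

* Levenberg–Marquardt damped least squares with an analytic Jacobian;
  relative-SSE tolerance 1e-10.
* Multi-start: one moment-based start (referent-cell mean for α₀,
  group-mean contrasts for the other α's, observed GM reductions clipped
  to [0, 0.85] for the β's) plus `n_random_starts` (default 10) seeded
  random admissible starts; the lowest SSE wins. The multiplicative form
  is non-convex but benign; in testing the moment start alone almost
  always reaches the global optimum.
* Covariates constant in the data (e.g. every applicator mixed) are
  dropped and listed in `omitted_terms_`; their coefficients are `None`.
* β's are unconstrained during optimisation; a solution with
  β₁ + β₂ ≥ 1 is flagged `admissible_ = False` rather than rejected.
  Predictions from such a fit can be negative; `predict_eq1` raises
  unless `allow_negative=True` (rank-based uses are unaffected).
* Per-parameter p-values come from asymptotic standard errors
  (`s²(JᵀJ)⁻¹`, t distribution with n − p df); `r_squared_` is
  1 − SSE/SST. No bootstrap or robust errors are attempted.

## The synthetic monitoring campaign

`SimConfig`/`simulate` emulate a small observational monitoring campaign
of the kind used to calibrate the v2 weights:

* **Cells.** Applicators are allocated exactly to (method, CR-glove)
  cells; the default layout is the 2,4-D campaign: boom spray 32 gloved /
  14 ungloved, hand spray 21 / 21 (88 application days).
* **Other factors.** Mixing (83/88 ≈ 0.94), repair (26/88 ≈ 0.30) and
  any-other-PPE (0.5, unreported in the source material and set to an
  agnostic coin flip) are independent Bernoulli draws. Mixers are coded
  `mix_ge50`; other PPE is one randomly chosen non-glove item, mirroring
  the model's single binary "other PPE" term.
* **Concentrations.** `conc = μ · exp(ε)`, `ε ~ N(0, ln GSD)`, with μ the
  model mean above — i.e. the model mean is the lognormal *median*, so
  simulated cell GMs converge to the model means and match GM-based
  summaries. Default GSD 3.5 (mid-range of the observed per-cell GSDs,
  3.0–4.9); GSD 1 gives exactly noise-free data, the round-trip target
  for the fitter.
* **True parameters.** Defaults are the published 2,4-D coefficients
  α = (27, 58, 123, 32) and β₁ = 0.75, with β₂ trimmed from the published
  0.26 to 0.24: the published point estimates sum to 1.01, which would
  imply a negative mean for a gloved applicator wearing other PPE; a
  generating model requires β₁ + β₂ < 1. `TrueParams` validates
  positivity of the mean over all 2⁵ factor combinations.
* **Reproducibility.** Everything derives from `seed` via
  `numpy.random.default_rng`; identical configs give identical cohorts
  and byte-identical output files.

What the generator does *not* emulate: background/pre-application urine
levels and carryover from unmonitored prior use, pharmacokinetic time
courses, repeated measurements on the same applicator (application days
are independent units), per-item PPE effects, and any dependence of
concentration on the specific analyte. Passing tests therefore show that
the pipeline recovers the structure it assumes — not that the algorithm
is valid for field data with those complications.

## Evaluation statistics

* **GM/GSD** — `exp(mean(ln v))` and `exp(sd(ln v))` (n−1 denominator);
  GSD is undefined (NaN) for a single observation.
* **Two-way ANOVA** — main effects of glove use and method on
  log-concentration, no interaction (the evaluation asks what each factor
  does *controlling for the other*); partial F tests, which coincide with
  Type III/II sums of squares for a main-effects model on unbalanced
  data. Backed by statsmodels OLS; verified in tests against explicit
  model-comparison sums of squares.
* **Calibration arithmetic** — percent reduction `100·(1 − a/b)`,
  GM ratio `a/b`, percent increase `100·(a/b − 1)`, rounded half away
  from zero at the precision such tables print (integer percent, one
  decimal for ratios).
* **Spearman correlation** — average ranks for ties (scipy); NaN for a
  constant vector rather than an arbitrary number.
* **Trend test** — Cuzick-type rank test across ordered groups with
  integer group scores 1, 2, …, tie-corrected variance, two-sided normal
  p-value; an exact permutation null is available for n ≤ 10 and is the
  oracle the normal approximation is tested against. The statistic
  depends on ranks only, hence is invariant to monotone transforms of
  the response.
* **Pipeline** (`evaluate_monitoring`, `expintensity evaluate`) — emits
  the method×glove summary, ANOVA, the correlation matrix of v1/v2
  scores with concentrations and model predictions, the model fit table,
  and the score-category summary with the trend test. Records a version
  cannot score (unassigned v1 methods) get NaN scores in the evaluation
  and are excluded pairwise from correlations; outputs embed tool
  version, weight-table versions and seed.

## Problem sizes used in simulation-based tests

Simulation-backed tests use 88-day campaigns (the default cell layout):
1000 replicate fits for the glove-reduction recovery check (median β̂₁
within 0.1 of 0.75), 1000 replicates for the category-trend power check,
5000 null replicates for the trend test's type-I error calibration
(empirical size within [0.03, 0.07] at α = 0.05), and 200 replicates for
ANOVA power. A 10⁴-observation single cell checks that empirical GM and
GSD converge to their targets within 5%.

## Known limitations

* Weights apply to all pesticides alike; no pesticide-specific weighting
  or absorbed-dose/pharmacokinetic modelling is attempted (scores are
  relative intensities, not internal doses).
* The raw-scale least-squares fit can be strongly influenced by the
  right tail of lognormal data at realistic GSDs; β̂₁ is nevertheless
  median-unbiased to within 0.1 at the default conditions, which is the
  property the evaluation relies on.
* With β₁ + β₂ near 1, the gloved+other-PPE cell mean sits near zero and
  individual fits occasionally land inadmissible; they are flagged, not
  silently corrected.
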