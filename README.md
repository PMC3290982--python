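# expintensity

Questionnaire-based pesticide **exposure-intensity scoring** for
epidemiologic cohorts, plus the statistical machinery to evaluate such an
algorithm against biomarker monitoring data.

Large agricultural cohorts cannot measure every participant's pesticide
exposure, so they estimate *relative* exposure intensity from
questionnaire responses: how often the applicator mixed or loaded
pesticides, which application methods they used, whether they repaired
application equipment, and which personal protective equipment (PPE) they
wore. The Agricultural Health Study (AHS) algorithm combines these as

```
intensity score = (MIX + APPLY + REPAIR) × PPE
```

where MIX, APPLY and REPAIR are tabulated weights and PPE is a reduction
multiplier, `1 −` the summed protective-equipment reduction fractions,
never removing more than 90% of exposure. Scores multiplied by lifetime
days of use give *intensity-weighted days*, the exposure metric used in
cohort analyses.

The package ships both frozen versions of the weight table:

* **version 1** — the original expert-judgment weights (scores 0.1–20;
  chemically-resistant (CR) gloves reduce exposure 40%);
* **version 2** — the revision calibrated against field monitoring of
  2,4-D and chlorpyrifos applicators (integer scores 1–220; CR gloves
  60%, boom spray raised to 40, airblast raised to 150, mixing lowered to
  50 relative to hand spray's 90).

Around the scorer it implements the full evaluation pipeline used to
justify such a revision: geometric-mean / GSD summaries by application
method and glove use, two-way ANOVA on log concentrations, GM-ratio and
percent-reduction calibration arithmetic, Spearman correlations between
score versions and biomarker levels, a Cuzick-type nonparametric trend
test across score categories, and the multiplicative nonlinear regression

```
Y = (α₀ + α₁·Mix + α₂·Method + α₃·Repair) × (1 − β₁·Gloves − β₂·PPEother)
```

of post-application urine concentration (µg/L) on the algorithm's binary
component variables. A synthetic-cohort generator emulates a monitoring
campaign (cells of method × glove use, lognormal concentrations whose
median follows the model above) so the whole pipeline runs end-to-end
without field data.

## Worked example

```python
from expintensity import ApplicatorRecord, IntensityScorer

scorer = IntensityScorer(version="v2").fit()
for mix, method in [("mix_ge50", "boom_on_tractor"),
                    ("mix_ge50", "hand_spray"),
                    ("did_not_mix", "air_blast")]:
    rec = ApplicatorRecord(id=method, mix_level=mix, methods=(method,))
    print(f"{mix:12s} {method:16s} -> {scorer.score_record(rec):g}")
```

prints

```
mix_ge50     boom_on_tractor  -> 90
mix_ge50     hand_spray       -> 140
did_not_mix  air_blast        -> 150
```

A frequent mixer applying by tractor boom scores 50 + 40 = 90; a mixer
hand-spraying scores 50 + 90 = 140; an airblast applicator scores 150
even without mixing — by construction the method with the highest
exposure potential under all scenarios. `IntensityScorer` follows the
sklearn transformer contract (`fit`/`transform`/`get_params`), and
`Eq1Regressor` is the matching estimator for the multiplicative
regression.

The same from the command line, plus a full synthetic evaluation:

```
$ expintensity simulate --seed 7 --out mon.csv     # 88-row campaign
$ expintensity evaluate mon.csv --seed 7 --out-dir eval
$ cat eval/report.txt
Two-way ANOVA on log concentration (main effects):
  CR glove use: F = 52.335, p = 1.916e-10
  Application method: F = 16.516, p = 0.0001072
Trend across score categories (v2): z = 7.066, p = 1.592e-12
Model fit R-squared = 0.204, n = 88
```

The glove and method effects planted by the generator are recovered as
strongly significant, and the geometric mean concentration rises across
the `<50 / 50–100 / >100` score categories (3.2, 68.3, 255.2 µg/L in this
run — see `eval/summary_category.csv`) with a sharply significant trend.
`expintensity range --weights v2` prints the achievable score range
`1 220` by exhaustive enumeration of every factor combination.

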