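# bcrisk

Validation tooling for multifactorial 10-year breast-cancer absolute-risk
models, built for biostatisticians who want to study — end to end, and
without access to restricted individual-level cohort data — how such a model
behaves in a prospective cohort: how well it is calibrated, how well it
discriminates under right-censoring, and how it stratifies women into
guideline risk categories.

The package has three parts:

1. **A declared multiplicative risk engine.**  A woman's hazard is the
   population age-specific incidence `λ(age)` scaled by a multiplicative
   relative risk combining a standardized polygenic risk score
   (`exp(β·z)`, per-SD hazard ratio `e^β`), rare pathogenic variants in
   *BRCA1*, *BRCA2*, *PALB2*, *ATM*, *CHEK2*, *RAD51C*, *RAD51D* and *BARD1*
   (highest-risk gene only), nine categorical questionnaire factors, and a
   first-degree family-history count.  Every factor is normalized so its
   population-mean relative risk is exactly 1, so missing values contribute
   the population-average effect and the model-average incidence reproduces
   the population incidence.  The 10-year absolute risk over a window
   `[a+1, min(a+11, 80))` is `1 − exp(−RR·Λ)` with `Λ` the cumulative
   population hazard (the first year is excluded to drop prevalent cancers;
   windows truncate at the censoring age for unaffected women).
2. **A synthetic prospective-cohort generator** emulating a large volunteer
   cohort of women aged 40–70 (entry-age structure, PRS ~ N(0,1), per-gene
   carrier frequencies of order 0.05–0.5%, realistic questionnaire
   missingness, ~3% 10-year incidence), with outcomes drawn by exact
   inverse-transform sampling from each woman's piecewise-constant hazard,
   optional age-group hazard excesses (e.g. +58.19% below age 50), a
   competing censoring process, and prospective-design eligibility rules.
3. **The validation battery.**  Expected/observed case ratio with the
   Poisson normal-approximation CI `(E/O)·exp(±1.96/√O)`; calibration slope
   (logistic regression of outcome on logit of predicted risk); decile
   calibration with exact binomial CIs; Mann–Whitney AUC with a DeLong CI;
   Harrell's C for censored follow-up; NICE-style risk-category tables
   (relative-risk cuts 1.6/3.1, absolute 10-year cuts 3%/8% and 5.8%/11%)
   and top-k% case-capture summaries.

## Worked example

Simulate a cohort under the package's default model, predict 10-year risks
with the full factor set, and validate the predictions against the simulated
outcomes:

```python
import bcrisk
from bcrisk import CohortConfig, simulate_cohort, predict_cohort
from bcrisk.validation import expected_observed, calibration_slope, auc

table = bcrisk.packaged_incidence_table()
model = bcrisk.default_model()

cohort, excluded = simulate_cohort(CohortConfig(n_women=20_000, seed=7), model, table)
pred = predict_cohort(cohort, model, table, factors_enabled="FH+QRF+PRS+PV")

eo = expected_observed(pred["abs_risk"], cohort["event"])
slope, s_lo, s_hi = calibration_slope(pred["abs_risk"], cohort["event"])
a, a_lo, a_hi = auc(pred["abs_risk"], cohort["event"])

print(f"women: {len(cohort)}  cases: {eo.observed}")
print(f"E/O   = {eo.ratio:.2f} (95% CI {eo.ci_low:.2f} to {eo.ci_high:.2f})")
print(f"slope = {slope:.2f} (95% CI {s_lo:.2f} to {s_hi:.2f})")
print(f"AUC   = {a:.2f} (95% CI {a_lo:.2f} to {a_hi:.2f})")
```

Output:

```
women: 19926  cases: 662
E/O   = 0.98 (95% CI 0.91 to 1.05)
slope = 0.97 (95% CI 0.86 to 1.09)
AUC   = 0.67 (95% CI 0.65 to 0.69)
```

Because the cohort was simulated under the prediction model itself, expected
and observed counts agree (E/O ≈ 1), the risk spread is correct (slope ≈ 1),
and the AUC reflects the information carried by the risk factors.  Feeding
the generator an age-group hazard excess instead (for example
`age_multipliers=[(0, 50, 1.5819)]`) produces the classic signature of a
cohort whose younger women exceed the population incidence: E/O drops below
1 in the under-50 stratum while the 50+ stratum stays near 1.

The same pipeline is available from the shell:

```bash
bcrisk run-all --seed 7 --out myrun        # simulate -> predict -> validate -> classify
bcrisk simulate --out cohort.csv --seed 7  # individual stages
bcrisk predict --cohort cohort.csv --out pred.csv
bcrisk validate --cohort cohort.csv --pred pred.csv --out report.csv
```

`run-all` writes one run directory containing the cohort, per-variant
predictions, the tidy validation report (one row per model variant and
stratum), decile-calibration tables, classification tables, and a
`manifest.json` recording the config hash, seed, versions and per-stage row
counts.

## Caveats

The risk engine is a simplified surrogate with declared, config-driven
effect sizes — not a reimplementation of any published pedigree-likelihood
model — and the bundled incidence table is illustrative, not national
statistics.  See `docs/methods.md` for the model, the generator's study
conditions, numerical conventions and known limitations.
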