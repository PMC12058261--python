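# Methods

## Scope and model

`bcrisk` implements a simplified multifactorial absolute-risk engine for
female breast cancer and the apparatus needed to validate such a model in a
prospective cohort.  It deliberately does **not** reimplement any published
pedigree-likelihood model: the genetic and epidemiological effects are
declared, config-driven multiplicative hazard ratios.  What the package is
faithful about is the *validation methodology* — the prediction-window
conventions, eligibility rules, calibration and discrimination statistics,
and risk-classification schemes used when such models are evaluated against
cohort data.

### Hazard model

A woman's breast-cancer hazard at age `t` is

    h(t) = λ(t) · RR,    RR = RR_PRS · RR_PV · Π_f RR_f

where `λ(t)` is the age-specific population incidence (piecewise constant on
the bands of an incidence table) and the relative-risk factors are:

* **PRS**: `RR_PRS = exp(β·z) / exp(β²/2)` for standardized score `z`.  The
  divisor is `E[exp(βZ)]` under `Z ~ N(0,1)`, so the population-mean PRS
  effect is exactly 1.  Raw scores are standardized with the published
  population constants (mean −0.424, SD 0.603).  Default `e^β = 1.61` per SD.
* **Pathogenic variants**: per-gene hazard ratios (defaults 5.0 *BRCA1*,
  4.0 *BRCA2*, 3.5 *PALB2*, 2.3 *CHEK2*, 2.0 *ATM*, 1.8 *RAD51C*/*RAD51D*/
  *BARD1*); a woman flagged in several genes is assigned the highest-risk
  gene only.  Normalized by the population-mean carrier effect computed from
  the declared carrier frequencies.
* **Questionnaire factors and family history**: per-category hazard ratios
  divided by the frequency-weighted category mean, so each factor's
  population-mean effect is exactly 1.

Two consequences of the normalization are load-bearing: a missing value
contributes exactly the population-average effect (a factor of 1), and the
population-mean combined relative risk is 1, so the model-average incidence
equals the population incidence and the calibrated baseline is `λ(t)` itself
(`calibrate_baseline` also supports un-normalized models, dividing by the
analytic mean relative risk).

Effect sizes are package defaults chosen to give the qualitative
discrimination ordering observed for models of this type — PRS the most
discriminative single factor, family history and questionnaire factors
similar and weaker — and are not estimates from any dataset.  An optional
age-knot mechanism can attenuate a factor's log hazard ratio linearly with
age; it is off by default.

### Prediction windows

A woman recruited at age `a` is predicted over `[a+1, min(a+11, 80))`:
10-year risk starting one year after recruitment (excluding prevalent
cancers) and capped at age 80.  For women censored unaffected before the
window end, the window truncates at the censoring age; incident cases keep
the full window.  The absolute risk is `1 − exp(−RR·Λ)` with `Λ` the exact
band-arithmetic cumulative hazard — no numeric quadrature, no competing
mortality (risks are cause-specific cumulative incidences).  Intervals are
half-open throughout.

### Incidence tables

Tables are contiguous half-open age bands with rates per 100,000
woman-years, optionally labelled with a calendar period (period-specific
analyses switch whole tables; no interpolation).  The packaged table is a
smooth synthetic curve — *not* national statistics — shaped like a
European registry schedule, with a 10-year risk of ≈3.6% at age 58 so that
relative-risk thresholds 1.6/3.1 correspond to 10-year absolute thresholds
near 5.8%/11%, and a lifetime (20–80) cumulative hazard of ≈0.124 so the
17%/30% lifetime cuts map to hazard multipliers ≈1.50/2.87 (close to the
conventional 1.6/3.1).

## Synthetic cohort generator

The generator emulates the structure of a large UK volunteer cohort of women
aged 40–70:

* entry ages drawn uniformly within 5-year bands weighted
  7.6/13.0/15.7/18.1/24.2/21.3% (40–44 … 65–69);
* standardized PRS ~ N(0,1); per-gene carrier draws at the default
  frequencies (0.04%–0.44%); questionnaire categories and a 0/1/2+
  family-history count (12% any family history) from the declared
  frequencies; independent per-factor missingness patterned on
  questionnaire completeness (e.g. 44% menopause age, 45% hormone-therapy
  use, 20% alcohol; age at first birth is structurally missing for
  nulliparous women);
* outcomes by exact inverse-transform sampling from each woman's
  piecewise-constant hazard `b(age)·RR·multiplier(age)` on the union of
  incidence-band and multiplier-band edges.  The optional age-group
  multiplier applies at the woman's *current* age, so a cohort with a +58.19%
  excess below 50 shows attenuated excess in women who age past 50 during
  follow-up — exactly the mechanism that makes an under-50-at-entry stratum
  underpredicted (E/O < 1) while the 50+ stratum stays near 1;
* censoring: one competing exponential process (default 0.0015/yr) whose
  draws are labelled loss / death / other-cancer / mastectomy in
  configurable shares, plus an administrative linkage end drawn uniformly
  10.5–14.5 years after entry (a staggered recruitment window against a
  fixed linkage date), plus the window end (`entry+11`) and age 80.  An
  optional Gompertz mortality process is available but off by default;
* eligibility rules applied in order with a per-rule exclusion tally:
  entry age in [40, 70); no prior cancer; no prophylactic mastectomy; no
  event within the first year (prevalent-cancer proxy); follow-up > 1 year.

Seeding: one master seed spawns independent child streams (profiles, events,
missingness) via `numpy.random.SeedSequence`, so stages are individually
reproducible and an identical config + seed yields a byte-identical cohort
CSV.  At the defaults the case fraction is ≈3.2% over the 10-year windows
and mean follow-up ≈10.5 years.

What the generator does **not** emulate: genotypes or sequence data,
mammographic density, pedigree structure beyond the summary count,
non-European populations (a miscalibration scenario — hazard multiplier plus
attenuated PRS effect — is the only stand-in), correlation between risk
factors (factors are sampled independently), and informative censoring.
Passing tests therefore demonstrate the statistical machinery is correct
under these idealized conditions, not that any particular risk model is
valid in real data.

### The calibration slope under censoring

The pairing convention (truncated windows for censored women, full windows
for cases) makes E/O essentially unbiased under independent censoring, but
gives the calibration slope a small *structural upward bias*: a
truncated-window record can never be a case (a woman with an earlier event
would have been recorded as a case with a full window), so observed risk
under-runs predictions at truncated low predictions and the fitted slope
steepens.  A controlled experiment with a perfectly specified model and 5%
of women censored uniformly in-window yields slope ≈ 1.05.  The effect is
proportional to the mid-window censoring mass; under the default conditions
(≈1.5% exponential censoring, linkage truncation only near the window end)
the residual bias is ≈ +0.02, within the Wald CI at n = 50,000.  This is a
property of the evaluation convention itself, worth remembering when
interpreting published calibration slopes from designs with substantial
early censoring.

## Validation statistics

* **E/O**: `E = Σ predicted risk` over each woman's own window,
  `O = Σ events`; 95% CI `(E/O)·exp(±1.96/√O)` (normal approximation to the
  Poisson distribution for `O`).  `O = 0` raises, with guidance to report E
  alone.
* **Calibration slope**: maximum-likelihood logistic regression of outcome
  on `logit(predicted risk)` with intercept (statsmodels), Wald 95% CI.
  Predictions exactly 0 or 1 and complete separation raise named errors.
* **Decile calibration**: stable ranking, equal-count groups with the
  remainder spread over the lowest groups, exact (Clopper–Pearson) binomial
  CIs for observed proportions.
* **AUC**: Mann–Whitney estimator with ties counted 1/2; CI from the DeLong
  placement-value variance decomposition.  Outcome is case-by-window, which
  can overstate discrimination when many windows are censored short — the
  reason Harrell's C is also reported.
* **Harrell C**: a pair is comparable iff the earlier exit is an event
  (event beats censoring at a tied time; two tied events are not
  comparable); prediction ties count 1/2.  CI via a leave-one-subject-out
  jackknife on the concordance U-statistic.  Follow-up time is measured from
  entry.  The implementation is an O(events × n) vectorized sweep validated
  against exhaustive pair enumeration and against lifelines.
* **Report**: one row per (model variant, stratum); empty strata yield NA
  rows rather than silent drops.  Display rounding is half-away-from-zero to
  2 decimals.

## Risk classification

Three ordered categories (near-population / moderate / high) under either
relative thresholds — the ratio of the individual window risk to the
population risk over the *same exact window* (no 5-year band discretization;
the woman's own window is both numerator and denominator) — or absolute
10-year thresholds (3%/8% guideline cuts, or 5.8%/11% matching the relative
cuts at the cohort median age of 58).  Boundary values go to the higher
category (`cut_low ≤ v < cut_high` is moderate).  `scheme_from_lifetime`
maps lifetime-risk cuts to hazard multipliers through
`r = −ln(1−c)/Λ_lifetime`, with the lifetime window `[20, 80)` by default
(the accumulation start age is a parameter, since guideline equivalences do
not fix it).  Top-k% capture ranks descending with stable ties and takes
`⌈k·n⌉` women.

## Numerical and design choices

* Exact band arithmetic everywhere; `1 − exp(−x)` via `expm1` for small
  risks.
* Inverse-transform event sampling is exact on the integration grid;
  zero-hazard tables produce no events.
* Logistic fits: Newton/IRLS via statsmodels, convergence and separation
  checked; an independently coded Newton–Raphson oracle agrees to 1e−8 in
  tests.
* Problem sizes: the test suite uses n = 50,000 cohorts for replicate-based
  checks (50 replicates for self-consistency coverage, 20 for the
  incidence-excess scenario), n = 100,000–200,000 for single-run
  parameter-recovery checks, and n ≤ 30 for the 500-instance brute-force
  equivalence suite; these sizes give Monte-Carlo error comfortably inside
  the asserted tolerances.
* CSV is the only output format; floats are written with pandas defaults
  (shortest round-trip repr) or `%.10g` for cohort files, and read back with
  the round-trip parser, so write → read → write is byte-stable.

## Known limitations

* The surrogate has no pedigree likelihood, no mammographic density, no
  tumour-subtype or ovarian/pancreatic outputs, and no competing-mortality
  adjustment in absolute risks.
* The bundled incidence table is illustrative; analyses of real populations
  must supply registry tables.
* Factor independence in the generator overstates the information added by
  each factor relative to correlated real data.
* The AUC for censored-horizon outcomes and the calibration-slope
  convention bias above are inherent to the evaluated design, not removable
  by implementation.
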