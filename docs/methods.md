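# Methods

This note records the model, the calibration machinery, the numerical
choices, and what the synthetic data do and do not establish.

## The evaluation model

The analysis compares children diagnosed with juvenile idiopathic
arthritis **within 6 months** of actively seeking treatment (`lt6`) against
those waiting **6+ months** (`ge6plus`), from a health-funder perspective
in 2023 AUD.

**Utilities.** CHU9D responses (nine dimensions — worry, sadness, pain,
tiredness, annoyance, school, sleep, daily routine, activities — each on
levels 1–5) are scored additively: `U = Σ_d w_d(L_d)`.  The bundled value
set pins each dimension's level-1 and level-5 weights to the published
per-dimension ranges (worry 0.11–0.22, … sleep −0.05–0.06) and
interpolates levels 2–4 linearly.  Under these ranges the best health
state scores 1.02 and the worst 0.00; the published ceiling of 1.00
reflects rounding of the printed ranges, and we deliberately do **not**
renormalise — the published value set can replace the bundled CSV without
code change.  Incomplete responses are excluded (no imputation), mirroring
the survey's analysis of the 89% who completed the instrument.

**Costs.** Annual utilization is priced item-by-item from a unit-cost
schedule split into four categories: medical investigations, health
professional visits, hospitalizations, medications.  Two survey rules are
modelled: (i) the Medicare Safety Net as a per-participant rebate uplift
(default +15%) on schedule-fee categories, triggered by the survey flag,
not by tracking out-of-pocket spend; (ii) participants using allied health
are assumed to hold a chronic-disease care plan, adding the care-plan
rebate item to their primary-care costs.  Medication regimens cost
whole dispensed packs per year (`ceil(dose × frequency / pack size)`);
corticosteroid injections/infusions are excluded from the medication rows
because they are assumed to be included in hospitalisation costs.  Unit
prices are plausible placeholders (the official MBS/PBS/NEP schedules are
data, not code); all calibration targets are the published component
means, not item fees.

**Lifetime projection.** Outcomes measured once at the survey are assumed
constant to death — the published analysis's conservative reading of its
lifetime horizon.  Remaining years come from a life table interpolated
linearly in age; discounting is end-of-year at rate `r` (base 5%), with a
fractional terminal year prorated at its discount factor:
`A(r, y) = Σ_{t=1..⌊y⌋} (1+r)^{-t} + (y−⌊y⌋)(1+r)^{-(⌊y⌋+1)}`.
Projection starts at **age at survey** (when utility and cost were
measured); `EconParams(project_from="diagnosis")` exposes the alternative.

**Comparison.** Welch (unequal-variance) t intervals throughout — the
published group cost SDs differ by a factor of two, so pooling would be
wrong.  Sign conventions: QALY gains positive for the early group
(lt6 − ge6), cost *savings* positive for the early group (ge6 − lt6).
The adjusted model is OLS of the outcome on the group indicator, a
4-df B-spline in age at survey, gender, and their interaction — a spline
approximation to the survey's generalized additive model (the exact
smoother is out of scope).  The cost-effectiveness plane resamples
participants within group (seeded, 2,000 replicates by default); its point
estimate equals the analytic means by construction.

## The synthetic cohort generator

Participant-level survey data are available only on request, so every
downstream stage runs on synthetic cohorts whose *pipeline outputs* are
calibrated to the published group statistics.  The defaults are the study
conditions; they are not tuning knobs.

* **Group sizes**: binomial with p(delayed) = 61/163; at n ≥ 10 both arms
  are kept populated.
* **Delay measures**: the categorical bins (<1, 1–2, 3–5, 6–8, 9–12
  months; 1–2, 3–4, >5 years) get within-group probabilities that decay
  plausibly with delay; a continuous delay is drawn uniformly inside the
  chosen bin.  The age-derived onset-to-diagnosis delay adds a gamma
  "seek lag" (symptom onset → actively seeking; mean 0.3 y).  The lag SD
  default (0.7 y) was fixed once so the Pearson correlation between the
  two measures sits near the published 0.80; at n = 10,000 the realized
  r ≈ 0.80.
* **Ages**: onset and diagnosis-to-survey gaps are truncated normals whose
  location and scale are *solved* (vectorised truncated-normal moments +
  root finding) so the **truncated** mixture moments match the published
  means/SDs over the per-participant bounds (onset in [0, 16) with
  diagnosis before 16; survey age ≤ 25).  The published gap SD for the
  delayed group (4.8 y at mean 5.1) is not attainable under the survey-age
  cap with independent draws; the solver then takes the widest member with
  the mean exact — the mean is the calibration priority.  Reported onset
  and diagnosis ages are coarsened as the survey captured them: completed
  months up to age 1, nearest half-year to age 4, nearest whole year above
  (the capture rule is silent on (4, 5]; whole years are used for
  continuity).
* **CHU9D levels**: a cumulative-logit ordinal model with common cutpoints
  (−3, −1, 1, 3) on a latent severity `s_i = μ_g + τ_g z_i`, `z ~ N(0,1)`
  shared across the nine dimensions (levels conditionally independent).
  `(μ_g, τ_g)` are solved per group (Gauss–Hermite quadrature + nested
  bisection) so the *scored* utility has exactly the target mean and SD
  (0.59/0.44, SD 0.29).  Per-dimension means are emergent, not separately
  calibrated; they track the published dimension table qualitatively.
* **Utilization counts**: zero-inflated Poisson per cost component, all
  components sharing a per-participant gamma frailty (mean 1, variance
  v_g) that induces realistic cross-service correlation and cost
  overdispersion.  Component-level mean targets follow the published cost
  table, with professional-visit rows rescaled so each category subtotal
  matches its printed subtotal (the printed visit components do not sum to
  their printed subtotal — likely participant-level missingness; both
  recomputed and component-sum values are reported, never forced to
  agree).  A global scale and v_g are solved per group from **closed-form
  model moments** (gamma Laplace transforms handle the care-plan
  indicator's nonlinearity) so the *costed* annual total has exactly the
  target mean and SD, including safety-net and care-plan effects.  The
  blank bone-fracture cell for the early group is treated as zero observed
  cost, not missing.
* **Flags**: ~11.4% (21/184) missing CHU9D, assigned independently of
  group; safety-net flag Bernoulli(0.25); care plans universal (the cost
  table footnote assumes them); uveitis at the published group rates; 69%
  female independent of group.

`calibration_report` re-scores and re-costs a generated cohort and flags
any moment further than 3 standard errors from target (SE of the SD via
the fourth-moment formula, which matters for heavy-tailed costs).  At
n = 10,000 the default generator produces no flags.

**What the synthetic data do not show.** The generator reproduces group
*moments*, not the survey's joint distribution: no age–cost or age–utility
correlation within group, no geography/ethnicity structure, no informative
missingness, no child/proxy completion effects.  Passing tests establish
that the pipeline's arithmetic, statistics and calibration are correct —
not that the published effect estimates are unbiased in the real cohort.

## Bundled reference data (synthetic stand-ins)

* `chu9d_value_set_synthetic.csv` — the interpolated value set above.
* `unit_costs_2023_synthetic.csv` — placeholder 2023-AUD unit prices plus
  safety-net parameters (threshold $2,250, rebate fraction 0.15).
* `life_table_synthetic.csv` — Gompertz hazard (b = 0.09 plus a small
  background rate) with life expectancy at birth 84.5 y unisex (86.3
  female / 82.7 male), giving ≈ 73 remaining years at the cohort's mean
  survey age of 11.7 — consistent with the published lifetime-to-annual
  ratio 208,458 / 10,729 ≈ 19.4 at 5% (the 73-year annuity factor).

## Numerical choices

* Moment solves use `brentq` on monotone brackets (latent-severity
  location; frailty variance; truncated-normal scale) with nested
  mean-solves inside; all are deterministic and cached, so cohorts are
  byte-identical under a fixed seed.
* Probability-extreme arithmetic goes through `expit` and survival
  functions to avoid overflow/cancellation.
* Degenerate inputs are explicit: zero-variance groups return exact
  differences with p = 1 (equal) or 0; groups under two observations raise
  or report missing statistics; empty cohorts raise; negative ages, rates
  and counts raise.
* Problem sizes: Monte-Carlo analyses use cohorts of 10,000 participants,
  with 50 seeded replicates for the headline estimates and the
  parameter-recovery check — enough for Monte-Carlo standard errors of
  roughly 0.8K AUD on the lifetime savings (vs a published CI half-width
  of ~163K).
* Chi-squared tests use no continuity correction by default (2×2 tables
  with an expected cell < 5 fall back to Fisher's exact test, flagged);
  both choices are exposed.  No multiple-testing correction is applied in
  descriptive tables, matching the published analysis.
* Delay-bin midpoints (0.5, 1.5, 4, 7, 10.5, 18, 42, 72 months) are
  config-exposed; the published analysis states none.

## Known limitations

* The constant-difference lifetime assumption ignores treatment-era
  dynamics; the exclusion sensitivity scenario (drop participants surveyed
  within a year of diagnosis) probes only its short-term edge.
* The budget-impact calculation covers a single incident cohort with no
  multi-year discounting of successive cohorts.
* Societal/out-of-pocket costs, mortality differences by JIA status,
  half-cycle correction and age-varying utility trajectories are out of
  scope.
* The bundled schedules are synthetic; absolute component costs are only
  as meaningful as their calibration targets, though all incremental
  results depend on the calibrated totals rather than individual prices.
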