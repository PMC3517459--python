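# Methods

## The scoring procedure

The package implements the standard construction of an additive prognostic
point score for a right-censored survival endpoint, as used for
radiotherapy cohorts with spinal cord compression (SCC) from myeloma.

Patients are described by ten dichotomized factors: nine pre-treatment
factors (age ≤63 vs ≥64 years — the cohort median; gender; ECOG
performance status 1–2 vs 3–4; 1–2 vs ≥3 involved vertebrae; ambulatory vs
not ambulatory; other bone lesions; extraosseous lesions; interval from
myeloma diagnosis to radiotherapy ≤15 vs >15 months; time developing motor
deficits 1–14 vs >14 days) plus the radiation regimen (short vs longer
course). Every cut-point is configurable (`default_factors(...)`). The
ambulatory field carries three raw levels (without aid, with aid, not
ambulatory); the two walking sub-levels are pooled into "ambulatory" after
a survival-equivalence check (`merge_ambulatory_check`) that reports the
two sub-level 12-month Kaplan–Meier rates and a log-rank p. The pipeline
always proceeds with the pooled level and keeps the check as evidence;
a configurable decision threshold was deliberately not imposed because the
merge is part of the factor definition, not a data-driven choice.

The accrual-ordered cohort is split alternately: odd 1-based positions
form the test arm, even positions the validation arm. All estimation —
screening, Cox selection, per-level rates, grouping — happens on the test
arm; the validation arm only ever sees the frozen score.

Selection is two-stage: a univariate log-rank screen at α = 0.05, then a
joint Cox proportional-hazards fit of the screened-in factors keeping
those with Wald p < 0.05 or p ≤ 0.06 (the "strong trend" rule; the
boundary is inclusive on 0.06 exactly as stated, so p = 0.061 drops).
Covariates are coded 0 = favorable / 1 = unfavorable so risk ratios are
≥1-directed.

Each level of each kept factor scores `round_half_up(S12% / 10)` points,
where S12 is the level's 12-month Kaplan–Meier survival on the test arm.
Half-up rounding is the unique rule consistent with all six reference
cells (8.1→8, 6.0→6, 5.6→6, 8.4→8, 6.9→7). By default the percent is
itself rounded to an integer before entering the rule, matching how
published score tables present their inputs; `points_from="full"` feeds
the full-precision value instead. Totals are the per-factor sums; the
attainable set is computed by exact enumeration of level combinations.

Prognostic groups are intervals of the total. The shipped reference
grouping is A = 19–20, B = 21–23, C = 24 points. When a fitted table's
attainable totals fall outside those intervals, `SurvivalScoreModel`
derives a grouping with an explicitly labelled heuristic
(`derive_grouping`): adjacent totals whose test-arm 12-month rates differ
by less than a configurable gap (default 10 percentage points) are merged,
and interval bounds are stretched to cover the whole attainable range.
Published groupings are designed by inspection; the heuristic makes no
optimality claim and exists so the pipeline is total.

Validation applies the frozen table and grouping to the hold-out arm and
reports per-group rates, the validation-arm log-rank p, and absolute
per-group differences vs the test arm. The score is flagged
"reproducible" when every evaluable difference is ≤ `tolerance_pct`
(default 10 points — the literature says "very similar" without a number,
so the default is an order-of-magnitude choice, not a published constant).
The score table is a frozen dataclass, so non-re-estimation on the
validation arm holds by construction.

## Survival machinery

Self-contained implementations, each verifiable against brute-force
risk-set computations (see `tests/_oracles.py`):

- **Kaplan–Meier**: product-limit over distinct death times; a subject
  censored at a death time is still at risk for that death (deaths
  processed first — the convention of `lifelines` and R `survival`).
  Greenwood's formula supplies standard errors. `km_survival_at` is
  right-continuous (value at an event time is post-jump); asking beyond
  the last follow-up returns the last estimate with a warning. The median
  is the smallest death time with S ≤ 0.5, `None` when never reached.
- **Log-rank** (k groups): observed-minus-expected deaths accumulated at
  pooled death times with the hypergeometric covariance; the statistic is
  the quadratic form over k−1 groups (pseudo-inverse fallback when the
  covariance is singular); with no events anywhere χ² = 0, p = 1. Times
  with a risk set of one are skipped in the variance (0/0 guard).
- **Cox regression**: Newton–Raphson on the partial likelihood starting at
  β = 0, step-halving whenever a step would decrease the likelihood,
  convergence at max |gradient| < 1e-8 within 50 iterations. Breslow tie
  handling by default (simplest to verify by brute force), Efron behind
  `ties="efron"`. The linear predictor is max-shifted before
  exponentiation (cancels exactly in all ratios) to avoid overflow. Wald
  CIs: exp(β ± 1.96·se) from the inverse observed information. Constant
  columns are dropped with a warning; |β| > 10 raises a
  monotone-likelihood (separation) flag. `cox_score_test` evaluates
  U(0)²/I(0); on tie-free binary data this equals the two-group log-rank
  χ² exactly, an identity the tests assert to 1e-6.

Survival times are non-negative reals in months throughout; integer-month
data are a special case, never an assumption.

The Table-4-style arm-comparison uses the Pearson chi-square on the 2×2
factor-by-arm table, without Yates correction by default (togglable).
Display percentages are rounded half-up; exact counts are kept alongside.

## The synthetic generator

`generate_cohort` emulates the reference study's data-generating process;
it is a pure function of its config (seed included).

- **Covariates**: per-factor Bernoulli draws of the unfavorable level at
  configured prevalences. The shipped calibration uses the reference
  arm margins (e.g. ECOG 3–4: 33/108 test, 38/108 validation). Optional
  pairwise odds-ratio coupling is available (`dependence`); it is solved
  sequentially with exact marginal correction, so marginals are preserved
  and pairwise ORs are matched (conditionally, when three or more factors
  are mutually coupled). Default is independence: the joint distribution
  was never published. Continuous fields (age, vertebra count, interval,
  motor-deficit days) are filled uniformly within their dichotomy side and
  carry no survival effect — none was prognostic in the reference data.
- **Survival**: exponential within stratum or linear-predictor cell — the
  minimal model with a closed form for rate calibration,
  λ = −ln(S₁₂)/12 per month. Three modes:
  `proportional_hazards` (baseline S₁₂ = 0.93, the best-group survival,
  times per-factor hazard ratios 2.09/2.14/1.97 for ECOG, ambulatory
  status and bone lesions), `stratum` (rate from the record's prognostic
  group truth: 49/74/93% test-style, 51/80/90% validation-style), and
  `ambulatory_sublevel` (rate from the raw ambulatory level, truths
  83/80/56%, to exercise the merge check against a configured truth —
  the stratum mode cannot express sub-level differences).
- **Censoring**: administrative censoring uniform on (0, 228) months
  (uniform accrual over a 19-year window with a fixed analysis date)
  plus independent exponential loss to follow-up at 0.009/month, chosen so
  roughly 15% of records are censored within 12 months. The reference
  study reports neither its censoring fraction nor follow-up distribution;
  these are assumptions, exposed in `CensoringConfig`.
- **Fixture**: `fixture_test_cohort()` is a deterministic 108-record
  cohort whose joint (ECOG × ambulatory × bone-lesion) cells are fixed so
  that scoring with the shipped table yields prognostic groups of exactly
  26/49/33 while matching the reference test-arm margins; all other
  fields are permuted to their margins from a fixed internal seed.

What the generator does **not** emulate: non-exponential hazard shapes
(no late plateaus or early excess mortality), covariate-dependent
censoring, calendar-time trends over the accrual window, measurement
error in the factors, and any covariate dependence beyond pairwise ORs.
Passing tests therefore demonstrate that the *pipeline* is correct and
recovers configured truths — not that the exponential model describes real
myeloma-SCC survival.

## Verification sizes and numerical checks

The test suite checks, among others: KM/log-rank/Cox equivalence with
brute-force oracles on instances of ≤8 subjects (1e-6); agreement with
`lifelines` on moderate data (1e-5, Efron ties); the score/log-rank
identity; log-rank type-I error under a 3×50 exponential null over 500
replicates (5% ± 2.5 points); stratum-mode KM recovery of all six group
truths within 2 percentage points at n = 10,000; and Cox recovery of the
three hazard ratios within 10% at n = 50,000. The simulation sizes were
chosen so Monte-Carlo error sits comfortably inside each tolerance for the
larger strata while keeping the suite fast; note the worst prognostic
group holds only ~8–10% of a cohort, so its KM rate at n = 10,000 has a
standard error near 2 points — the recovery check is deliberately strict
there.

## Known limitations

- At the reference scale (108-patient arms) factor selection is unstable:
  re-simulating the study shows different factor subsets screened in run
  to run, and per-group validation differences regularly exceed 10 points
  in the smallest group. This is a property of the methodology at that
  sample size, and the package reports it honestly rather than smoothing
  it over.
- No optimism correction (bootstrap or otherwise) of the score; the
  hold-out arm is the only guard against overfitting, as in the original
  methodology.
- Only two-level factors are supported (beyond the ambulatory 3→2 merge);
  missing values are validation errors, not imputed.
- No time-varying covariates, stratified Cox, frailty, or competing risks.
- The reference study's printed univariate/characteristics p-values cannot
  be re-derived without its patient-level data; the package computes its
  own (and documents that the printed Table-4-style chi-square p-values do
  not follow from the printed counts under either Pearson or Yates).
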