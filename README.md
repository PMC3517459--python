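# sccscore

Construction and hold-out validation of an additive survival point score
for patients irradiated for **malignant spinal cord compression (SCC) from
myeloma** — and, more generally, a tested implementation of the widely used
"rate/10" point-score methodology for radiotherapy cohorts.

Myeloma patients with SCC are treated with radiotherapy alone, and the
choice of regimen (single-fraction short courses vs 2–4 week longer
courses, or dose escalation) hinges on the patient's survival prognosis.
A practical way to estimate that prognosis is an additive point score built
from a handful of pre-treatment factors. This package implements the whole
scoring workflow for biostatisticians and clinical researchers who want to
build, stress-test, or re-derive such scores:

1. **Alternating split** of the accrual-ordered cohort into a test arm
   (odd positions) and a validation arm (even positions).
2. **Univariate screen** of ten dichotomized factors (age ≤63/≥64, gender,
   ECOG‑PS 1–2/3–4, 1–2/≥3 involved vertebrae, ambulatory status, other
   bone lesions, extraosseous lesions, interval from diagnosis to
   radiotherapy ≤15/>15 months, time developing motor deficits 1–14/>14
   days, and the radiation regimen) by Kaplan–Meier estimation and the
   log-rank test; keep factors with p < 0.05. The two ambulatory
   sub-levels (with/without aid) are pooled after a survival-equivalence
   check.
3. **Multivariate selection** with a Cox proportional-hazards model
   (partial likelihood maximized by Newton–Raphson; Breslow ties; Wald
   inference): keep factors with p < 0.05 or a strong trend p ≤ 0.06.
4. **Point assignment**: each level of each selected factor scores
   ⌊S₁₂(%)/10⌉ points (12-month Kaplan–Meier survival divided by ten,
   rounded half-up). A patient's total score is the sum over factors, and
   totals are stratified into prognostic groups (reference cut-points:
   A = 19–20, B = 21–23, C = 24 points).
5. **Hold-out validation**: the frozen table and grouping are applied to
   the validation arm and per-group 12-month rates are compared.

Because patient-level data behind such scores are generally unpublished,
the package ships a **calibrated synthetic-cohort generator**
(`sccscore.simulate`) reproducing the reference study's covariate margins
(108 patients per arm), hazard ratios (2.09 / 2.14 / 1.97 for ECOG,
ambulatory status and other bone lesions), and prognostic-group 12-month
survivals (49/74/93% test-style, 51/80/90% validation-style), so every
stage is testable end to end.

The survival machinery (Kaplan–Meier with Greenwood variance, k-group
log-rank, Cox regression with Breslow/Efron ties) is implemented directly
against the defining formulas and is verified in the test suite against
brute-force risk-set computations and against `lifelines`.

## Worked example

```python
import dataclasses
import sccscore as s

cfg = dataclasses.replace(s.reference_calibration("test", seed=42),
                          n=2000, survival_mode="proportional_hazards")
results = s.SurvivalScoreModel(s.generate_cohort(cfg)).fit()
print(results.summary())
```

```
Survival point score: fit summary
==================================================
cohort: n=2000 (test 1000, validation 1000)
ambulatory merge check: S12 without aid 85%, with aid 88%, log-rank p=0.92 -> merged

selected factors (joint Cox fit on the test arm):
  ecog                 RR  1.84  (95% CI 1.52-2.22)  p=0.000  [kept]
  ambulatory           RR  2.74  (95% CI 2.27-3.32)  p=0.000  [kept]
  bone_lesions         RR  2.14  (95% CI 1.76-2.59)  p=0.000  [kept]

score table (test arm 12-month rates -> points):
  ecog           1-2              S12  86.0%  -> 9 points
  ecog           3-4              S12  75.0%  -> 8 points
  ambulatory     ambulatory       S12  87.0%  -> 9 points
  ambulatory     not ambulatory   S12  69.0%  -> 7 points
  bone_lesions   no               S12  88.0%  -> 9 points
  bone_lesions   yes              S12  78.0%  -> 8 points
total score range: 23-27 (attainable: [23, 24, 25, 26, 27])

prognostic groups at 12 months:
  A (23-23 pts): test n= 28    29% | validation n= 51    49%
  B (24-25 pts): test n=365    75% | validation n=352    77%
  C (26-27 pts): test n=607    89% | validation n=597    89%
log-rank across groups: test p=8.1e-42, validation p=3.9e-31
per-group |test - validation| differences: {'A': 19.9, 'B': 2.0, 'C': 0.1}
reproducible at tolerance 10 pct points: False
```

Reading the output: the three factors carrying simulated hazards were
screened in and kept; each level got points from its 12-month test-arm
rate; totals 23–27 were stratified (the reference 19–24 cut-points do not
apply to this table, so a rate-gap heuristic derived the grouping — hence
the warning you will see); the frozen score transferred to the hold-out
arm with per-group differences of 19.9/2.0/0.1 points. The worst group
held only 28 test-arm patients, so its rate is noisy and the overall
reproducibility flag is (correctly) conservative at the default ±10
tolerance.

The shipped reference table itself behaves exactly as published:

```python
>>> table = s.reference_score_table()
>>> [e.points for e in table.entries]          # 81, 60, 56, 81, 84, 69 (%) -> points
[8, 6, 6, 8, 8, 7]
>>> rng = s.score_range(table)
>>> rng.min_total, rng.max_total
(19, 24)
>>> s.assign_groups([19, 21, 24])
['A', 'B', 'C']
```

There is also a CLI (`sccscore simulate | split | screen | build-score |
validate | run-all`), e.g.:

```bash
sccscore simulate --arm test --n 600 --seed 42 --mode proportional_hazards --out cohort.csv
sccscore run-all --input cohort.csv --out-dir out/
```

which writes the characteristics, univariate, Cox, score-table, group and
validation tables as CSV/JSON plus per-group Kaplan–Meier curve exports.

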