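"""Reference calibration: the published myeloma-SCC scoring study's printed numbers.

The motivating study irradiated 216 unselected patients with spinal cord
compression from myeloma (accrued 1992-2011) and split them alternately
into a 108-patient test arm and a 108-patient validation arm. Its printed
arm-level covariate counts, multivariate risk ratios, per-level 12-month
survival rates and prognostic-group survival rates are collected here as
the package's reference calibration: they parameterize the synthetic
cohort generator and provide the shipped score table. Patient-level data
were never deposited, so these marginals are all that can be carried over.
"""

from __future__ import annotations

from .score import DEFAULT_GROUPING, PrognosticGrouping, ScoreTable

#: Arm size of the reference study (each of test and validation).
ARM_N = 108

#: Count of the unfavorable level per factor, by arm (out of 108 each).
UNFAVORABLE_COUNTS = {
    "test": {
        "age": 51, "gender": 38, "ecog": 33, "vertebrae": 60,
        "ambulatory": 27, "bone_lesions": 63, "extraosseous": 3,
        "interval": 50, "motor_deficit_time": 46, "regimen": 37,
    },
    "validation": {
        "age": 54, "gender": 42, "ecog": 38, "vertebrae": 58,
        "ambulatory": 32, "bone_lesions": 65, "extraosseous": 6,
        "interval": 49, "motor_deficit_time": 50, "regimen": 38,
    },
}

#: Pooled unfavorable-level prevalences (both arms, n = 216).
POOLED_PREVALENCES = {
    k: (UNFAVORABLE_COUNTS["test"][k] + UNFAVORABLE_COUNTS["validation"][k]) / (2 * ARM_N)
    for k in UNFAVORABLE_COUNTS["test"]
}

#: Multivariate hazard ratios (unfavorable vs favorable) of the three
#: factors retained in the score.
HAZARD_RATIOS = {"ecog": 2.09, "ambulatory": 2.14, "bone_lesions": 1.97}

#: Per-level 12-month survival rates (percent, test arm) behind the score.
SCORE_RATES = {
    "ecog": {"1-2": 81.0, "3-4": 60.0},
    "ambulatory": {"not ambulatory": 56.0, "ambulatory": 81.0},
    "bone_lesions": {"no": 84.0, "yes": 69.0},
}

#: Multivariate Wald p-values reported alongside the selection.
SELECTION_P = {"ecog": 0.036, "ambulatory": 0.037, "bone_lesions": 0.06}

#: True 12-month survival per prognostic group used in stratum-mode
#: simulation, per arm style.
GROUP_S12 = {
    "test": {"A": 0.49, "B": 0.74, "C": 0.93},
    "validation": {"A": 0.51, "B": 0.80, "C": 0.90},
}

#: 12-month survival of the ambulatory sub-levels (and the non-ambulatory
#: level) used by the ambulatory-merge simulation mode.
AMBULATORY_SUBLEVEL_S12 = {
    "not_ambulatory": 0.56,
    "ambulatory_with_aid": 0.80,
    "ambulatory_without_aid": 0.83,
}

#: Reference prognostic grouping (A: 19-20, B: 21-23, C: 24 points).
REFERENCE_GROUPING: PrognosticGrouping = DEFAULT_GROUPING


def reference_score_table() -> ScoreTable:
    """The shipped score table: points derived from the reference 12-month
    rates by the rate/10 half-up rule."""
    return ScoreTable.from_rates(SCORE_RATES, SELECTION_P)
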