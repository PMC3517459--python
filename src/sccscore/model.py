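"""Model / Results interface for the survival-score pipeline.

``SurvivalScoreModel`` wraps a full accrual cohort plus the analysis
configuration; ``fit()`` runs split -> ambulatory-merge check -> univariate
screen -> multivariate selection -> score table -> grouping -> hold-out
validation and returns a ``SurvivalScoreResults`` carrying every artifact
with a ``summary()`` table, in the spirit of statsmodels' model objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .cohort import (
    AmbulatoryMergeReport,
    Cohort,
    FactorDef,
    PatientRecord,
    alternate_split,
    characteristics_table,
    default_factors,
    merge_ambulatory_check,
)
from .score import (
    DEFAULT_GROUPING,
    CoxFit,
    GroupSurvival,
    PrognosticGrouping,
    ScoreRange,
    ScoreTable,
    UnivariateScreen,
    ValidationReport,
    assign_groups,
    build_score_table,
    derive_grouping,
    group_survival,
    multivariate_select,
    score_range,
    total_score,
    univariate_screen,
    validate_score,
)
from .survival import km_estimate, km_to_frame


class SurvivalScoreModel:
    """Additive survival point score built on an alternately-split cohort.

    Parameters
    ----------
    cohort
        The full accrual-ordered cohort; odd positions form the test arm
        on which the score is built, even positions the hold-out
        validation arm.
    factors
        Candidate dichotomized factors (defaults to the ten standard SCC
        factors with their usual cut-points).
    alpha_uni, alpha_mv, trend
        Log-rank screening threshold, multivariate Wald threshold, and the
        strong-trend threshold (factors with p <= trend are also kept).
    grouping
        Prognostic grouping to use. ``None`` uses the standard 19-20 /
        21-23 / 24 cut-points when the fitted table attains that range and
        otherwise falls back to a rate-gap heuristic with a warning.
    points_from
        "rounded" feeds integer-rounded 12-month percents to the point
        rule; "full" uses full-precision KM values.
    tolerance_pct
        Maximum per-group |test - validation| rate difference (percentage
        points) for the score to be flagged reproducible.
    """

    def __init__(
        self,
        cohort: Cohort,
        factors: list[FactorDef] | None = None,
        alpha_uni: float = 0.05,
        alpha_mv: float = 0.05,
        trend: float = 0.06,
        grouping: PrognosticGrouping | None = None,
        points_from: str = "rounded",
        tolerance_pct: float = 10.0,
        t_horizon: float = 12.0,
    ):
        if not 0 < alpha_uni < 1 or not 0 < alpha_mv < 1 or not 0 < trend < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if trend < alpha_mv:
            raise ValueError("trend threshold must be >= alpha_mv")
        self.cohort = cohort
        self.factors = factors if factors is not None else default_factors()
        self.alpha_uni = alpha_uni
        self.alpha_mv = alpha_mv
        self.trend = trend
        self.grouping = grouping
        self.points_from = points_from
        self.tolerance_pct = tolerance_pct
        self.t_horizon = t_horizon

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "", **kwargs) -> "SurvivalScoreModel":
        """Build from a patient-per-row DataFrame with the canonical columns."""
        records = []
        for _, row in df.iterrows():
            records.append(PatientRecord(
                patient_id=str(row["patient_id"]),
                age_years=int(row["age_years"]),
                gender=str(row["gender"]),
                ecog_ps=int(row["ecog_ps"]),
                n_involved_vertebrae=int(row["n_involved_vertebrae"]),
                ambulatory_status=str(row["ambulatory_status"]),
                other_bone_lesions=bool(int(row["other_bone_lesions"])),
                extraosseous_lesions=bool(int(row["extraosseous_lesions"])),
                interval_dx_to_rt_months=float(row["interval_dx_to_rt_months"]),
                motor_deficit_days=int(row["motor_deficit_days"]),
                radiation_regimen=str(row["radiation_regimen"]),
                survival_months=float(row["survival_months"]),
                death_observed=bool(int(row["death_observed"])),
            ))
        return cls(Cohort(records, label), **kwargs)

    def fit(self) -> "SurvivalScoreResults":
        test, validation = alternate_split(self.cohort)
        ambulatory_check = merge_ambulatory_check(self.cohort, t=self.t_horizon)
        characteristics = characteristics_table(test, validation, self.factors)
        screen = univariate_screen(test, self.factors, alpha_uni=self.alpha_uni)
        selected, cox = multivariate_select(
            test, self.factors, screen, alpha_mv=self.alpha_mv, trend=self.trend)
        table = build_score_table(test, selected, cox, points_from=self.points_from)
        rng = score_range(table)

        grouping = self.grouping
        if grouping is None:
            covered = all(self._covers(DEFAULT_GROUPING, t) for t in rng.attainable)
            if covered:
                grouping = DEFAULT_GROUPING
            else:
                warnings.warn(
                    "attainable totals fall outside the standard 19-20/21-23/24 "
                    "grouping; deriving a heuristic grouping from the test arm",
                    stacklevel=2,
                )
                grouping = derive_grouping(test, table, selected)

        test_groups = group_survival(test, table, selected, grouping, t=self.t_horizon)
        validation_report = validate_score(
            validation, table, selected, test_groups, grouping,
            tolerance_pct=self.tolerance_pct)
        return SurvivalScoreResults(
            model=self, test=test, validation=validation,
            ambulatory_check=ambulatory_check, characteristics=characteristics,
            screen=screen, cox=cox, selected_factors=selected,
            score_table=table, score_range=rng, grouping=grouping,
            test_groups=test_groups, validation_report=validation_report,
        )

    @staticmethod
    def _covers(grouping: PrognosticGrouping, total: int) -> bool:
        try:
            grouping.assign(total)
            return True
        except ValueError:
            return False


@dataclass
class SurvivalScoreResults:
    """Fitted score with all intermediate artifacts."""

    model: SurvivalScoreModel
    test: Cohort
    validation: Cohort
    ambulatory_check: AmbulatoryMergeReport
    characteristics: pd.DataFrame
    screen: UnivariateScreen
    cox: CoxFit
    selected_factors: list[FactorDef] = field(default_factory=list)
    score_table: ScoreTable = None
    score_range: ScoreRange = None
    grouping: PrognosticGrouping = DEFAULT_GROUPING
    test_groups: GroupSurvival = None
    validation_report: ValidationReport = None

    # -- prediction -------------------------------------------------------
    def predict_total(self, record: PatientRecord) -> int:
        """Total score of a (new) patient under the fitted table."""
        return total_score(record, self.score_table, self.selected_factors)

    def predict_group(self, record: PatientRecord) -> str:
        return self.grouping.assign(self.predict_total(record))

    def score_frame(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Totals and group labels for every record of a cohort (default: test arm)."""
        cohort = cohort if cohort is not None else self.test
        totals = [self.predict_total(r) for r in cohort]
        return pd.DataFrame({
            "patient_id": [r.patient_id for r in cohort],
            "total_score": totals,
            "group": assign_groups(totals, self.grouping),
        })

    # -- curves / plotting ------------------------------------------------
    def group_km_frames(self, arm: str = "test") -> dict[str, pd.DataFrame]:
        """Per-group KM curve tables for the requested arm."""
        cohort = {"test": self.test, "validation": self.validation}[arm]
        frame = self.score_frame(cohort)
        out = {}
        for g in self.grouping.labels:
            ids = set(frame.loc[frame["group"] == g, "patient_id"])
            recs = [r for r in cohort if r.patient_id in ids]
            if recs:
                out[g] = km_to_frame(km_estimate(
                    [r.survival_months for r in recs],
                    [r.death_observed for r in recs]))
        return out

    def plot_group_curves(self, arm: str = "test", ax=None):
        """Step plot of the per-group KM curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, frame in self.group_km_frames(arm).items():
            t = [0.0, *frame["time"]]
            s = [1.0, *frame["survival"]]
            ax.step(t, s, where="post", label=f"group {g}")
        ax.set_xlabel("months from start of radiotherapy")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(f"{arm} arm: prognostic-group survival")
        return ax

    # -- summary ----------------------------------------------------------
    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Survival point score: fit summary")
        add("=" * 50)
        add(f"cohort: n={len(self.test) + len(self.validation)} "
            f"(test {len(self.test)}, validation {len(self.validation)})")
        ac = self.ambulatory_check
        if ac.evaluable:
            add(f"ambulatory merge check: S12 without aid {ac.rate_without_aid:.0f}%, "
                f"with aid {ac.rate_with_aid:.0f}%, log-rank p={ac.p_logrank:.2f} -> merged")
        else:
            add(f"ambulatory merge check: not evaluable ({ac.note})")
        add("")
        add("selected factors (joint Cox fit on the test arm):")
        for name, rr, lo, hi, p in zip(self.cox.names, self.cox.risk_ratio,
                                       self.cox.ci95[:, 0], self.cox.ci95[:, 1],
                                       self.cox.p_wald):
            kept = "kept" if any(f.name == name for f in self.selected_factors) else "dropped"
            add(f"  {name:<20} RR {rr:5.2f}  (95% CI {lo:.2f}-{hi:.2f})  p={p:.3f}  [{kept}]")
        add("")
        add("score table (test arm 12-month rates -> points):")
        for e in self.score_table.entries:
            add(f"  {e.factor:<14} {e.level:<16} S12 {e.rate_12mo:5.1f}%  -> {e.points} points")
        rng = self.score_range
        add(f"total score range: {rng.min_total}-{rng.max_total} "
            f"(attainable: {sorted(rng.attainable)})")
        add("")
        add(f"prognostic groups at {self.test_groups.t:g} months:")
        vr = self.validation_report
        for label, lo, hi in self.grouping.intervals:
            rt = self.test_groups.rate.get(label)
            rv = vr.rate_validation.get(label)
            fmt = lambda x: f"{x:5.0f}%" if x is not None else "  n/a"
            add(f"  {label} ({lo}-{hi} pts): test n={self.test_groups.n[label]:>3} "
                f"{fmt(rt)} | validation n={vr.n_validation.get(label, 0):>3} {fmt(rv)}")
        p_t = self.test_groups.p_logrank
        p_v = vr.p_logrank_validation
        add(f"log-rank across groups: test p={p_t if p_t is None else format(p_t, '.3g')}, "
            f"validation p={p_v if p_v is None else format(p_v, '.3g')}")
        diffs = {g: d for g, d in vr.difference.items() if d is not None}
        add(f"per-group |test - validation| differences: "
            f"{ {g: round(d, 1) for g, d in diffs.items()} }")
        add(f"reproducible at tolerance {vr.tolerance_pct:g} pct points: {vr.reproducible}")
        return "\n".join(lines)
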