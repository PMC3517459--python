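"""Additive survival point score: construction, grouping, validation.

The scoring procedure, in the style used for radiotherapy prognostic
scores: (1) screen each dichotomized factor with Kaplan-Meier curves and
a two-group log-rank test; (2) put the screened-in factors jointly into a
Cox model and keep those significant (p < alpha_mv) or showing a strong
trend (p <= trend); (3) give each level of each kept factor
round_half_up(12-month survival % / 10) points; (4) a patient's total
score is the sum of their level points; (5) stratify totals into
prognostic groups; (6) freeze the table and grouping built on the test
arm and re-evaluate group survival on the hold-out validation arm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .cohort import Cohort, FactorDef
from .survival import (
    CoxFit,
    cox_fit,
    km_estimate,
    km_median,
    km_survival_at,
    logrank_test,
)


class PipelineError(RuntimeError):
    """A scoring-pipeline stage failed; carries the stage diagnostics."""


def level_points(rate_12mo: float) -> int:
    """Points for a factor level: its 12-month survival rate in percent
    divided by 10, rounded half-up to an integer."""
    if not 0.0 <= rate_12mo <= 100.0:
        raise ValueError(f"12-month survival rate must be in [0, 100], got {rate_12mo}")
    return round_half_up(rate_12mo / 10.0)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorScreen:
    """Per-level KM summary and log-rank p for one dichotomized factor."""

    factor: str
    levels: tuple[str, str]
    n: dict
    rate_6mo: dict        # percent per level
    rate_12mo: dict       # percent per level
    median: dict          # months per level, None = not reached
    p_logrank: float
    selected: bool


@dataclass(frozen=True)
class UnivariateScreen:
    rows: tuple[FactorScreen, ...]
    alpha_uni: float
    excluded: tuple[str, ...] = ()

    @property
    def selected_factors(self) -> list[str]:
        return [r.factor for r in self.rows if r.selected]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for level in r.levels:
                recs.append({
                    "factor": r.factor, "level": level, "n": r.n[level],
                    "s6_pct": r.rate_6mo[level], "s12_pct": r.rate_12mo[level],
                    "median_months": r.median[level],
                    "p_logrank": r.p_logrank, "selected": r.selected,
                })
        return pd.DataFrame(recs)


def univariate_screen(
    cohort: Cohort,
    factors: list[FactorDef],
    alpha_uni: float = 0.05,
    t_rates: tuple[float, float] = (6.0, 12.0),
) -> UnivariateScreen:
    """KM per factor level, 6- and 12-month rates, median, log-rank p.

    A factor is screened in when its log-rank p < ``alpha_uni``. A factor
    with an empty level has no contrast and is excluded with a warning.
    """
    rows, excluded = [], []
    t6, t12 = t_rates
    for f in factors:
        per_level = {lvl: [r for r in cohort if f.level_of(r) == lvl] for lvl in f.levels}
        if any(len(v) == 0 for v in per_level.values()):
            warnings.warn(f"factor {f.name}: a level is empty; excluded from screen",
                          stacklevel=2)
            excluded.append(f.name)
            continue
        n, r6, r12, med = {}, {}, {}, {}
        for lvl, recs in per_level.items():
            curve = km_estimate([r.survival_months for r in recs],
                                [r.death_observed for r in recs])
            n[lvl] = len(recs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # rate horizon may pass last follow-up
                r6[lvl] = 100.0 * km_survival_at(curve, t6)
                r12[lvl] = 100.0 * km_survival_at(curve, t12)
            med[lvl] = km_median(curve)
        lr = logrank_test([
            ([r.survival_months for r in per_level[lvl]],
             [r.death_observed for r in per_level[lvl]])
            for lvl in f.levels
        ])
        rows.append(FactorScreen(
            factor=f.name, levels=f.levels, n=n, rate_6mo=r6, rate_12mo=r12,
            median=med, p_logrank=lr.p, selected=bool(lr.p < alpha_uni),
        ))
    return UnivariateScreen(rows=tuple(rows), alpha_uni=alpha_uni, excluded=tuple(excluded))


# ---------------------------------------------------------------------------
# Multivariate selection
# ---------------------------------------------------------------------------

def multivariate_select(
    cohort: Cohort,
    factors: list[FactorDef],
    screened: UnivariateScreen,
    alpha_mv: float = 0.05,
    trend: float = 0.06,
) -> tuple[list[FactorDef], CoxFit]:
    """Joint Cox fit on the screened-in factors; keep p < alpha_mv or p <= trend.

    Covariates are coded 0 = favorable, 1 = unfavorable, so risk ratios are
    >= 1-directed for the worse level. Non-convergence aborts the pipeline
    with the fit diagnostics attached.
    """
    by_name = {f.name: f for f in factors}
    selected_names = [nm for nm in screened.selected_factors if nm in by_name]
    if not selected_names:
        raise PipelineError("no factor passed the univariate screen; no score constructible")
    sel = [by_name[nm] for nm in selected_names]
    X = np.array([[f.indicator(r) for f in sel] for r in cohort], dtype=float)
    fit = cox_fit(X, cohort.times, cohort.events, names=selected_names)
    if not fit.converged:
        raise PipelineError(
            f"Cox fit did not converge in {fit.n_iterations} iterations "
            f"(max |gradient| not below tolerance); diagnostics: {fit.to_frame()}"
        )
    keep = [
        by_name[nm] for nm, p in zip(fit.names, fit.p_wald)
        if p < alpha_mv or p <= trend
    ]
    return keep, fit


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreEntry:
    factor: str
    level: str
    rate_12mo: float  # percent
    points: int


@dataclass(frozen=True)
class ScoreTable:
    """Frozen per-level points for the selected factors.

    Immutable by construction: once built on the test arm it is applied
    unchanged to any other cohort. ``p_multivariate`` carries the Wald p
    of each factor from the selection fit, when available.
    """

    entries: tuple[ScoreEntry, ...]
    p_multivariate: tuple[tuple[str, float], ...] = ()

    @property
    def factor_names(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.factor not in seen:
                seen.append(e.factor)
        return seen

    def points_for(self, factor: str, level: str) -> int:
        for e in self.entries:
            if e.factor == factor and e.level == level:
                return e.points
        raise KeyError(f"score table has no entry for factor {factor!r} level {level!r}")

    def factor_points(self, factor: str) -> list[int]:
        pts = [e.points for e in self.entries if e.factor == factor]
        if not pts:
            raise KeyError(f"score table has no factor {factor!r}")
        return pts

    @classmethod
    def from_rates(cls, rates: dict[str, dict[str, float]],
                   p_multivariate: dict[str, float] | None = None) -> "ScoreTable":
        """Build a table from per-factor, per-level 12-month rates (percent)."""
        entries = tuple(
            ScoreEntry(factor=f, level=lvl, rate_12mo=float(rate),
                       points=level_points(rate))
            for f, levels in rates.items() for lvl, rate in levels.items()
        )
        pmv = tuple((p_multivariate or {}).items())
        return cls(entries=entries, p_multivariate=pmv)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "factor": e.factor, "level": e.level,
            "s12_pct": e.rate_12mo, "points": e.points,
        } for e in self.entries])

    def to_json(self) -> str:
        return json.dumps({
            "entries": [e.__dict__ for e in self.entries],
            "p_multivariate": dict(self.p_multivariate),
        }, indent=2)


def build_score_table(
    cohort: Cohort,
    factors: list[FactorDef],
    fit: CoxFit | None = None,
    points_from: str = "rounded",
) -> ScoreTable:
    """Per-level 12-month KM rate on ``cohort`` and its points.

    ``points_from="rounded"`` (default) feeds the integer-rounded percent
    into the point rule, matching how published score tables present their
    inputs; ``"full"`` uses the full-precision KM value instead.
    """
    if points_from not in ("rounded", "full"):
        raise ValueError("points_from must be 'rounded' or 'full'")
    rates: dict[str, dict[str, float]] = {}
    for f in factors:
        rates[f.name] = {}
        for lvl in f.levels:
            recs = [r for r in cohort if f.level_of(r) == lvl]
            if not recs:
                raise PipelineError(f"factor {f.name}: level {lvl!r} empty on scoring cohort")
            curve = km_estimate([r.survival_months for r in recs],
                                [r.death_observed for r in recs])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rate = 100.0 * km_survival_at(curve, 12.0)
            rates[f.name][lvl] = float(round_half_up(rate)) if points_from == "rounded" else rate
    pmv = dict(zip(fit.names, fit.p_wald)) if fit is not None else None
    return ScoreTable.from_rates(rates, pmv)


def total_score(record, table: ScoreTable, factors: list[FactorDef]) -> int:
    """Sum of the record's level points over the table's factors."""
    by_name = {f.name: f for f in factors}
    total = 0
    for name in table.factor_names:
        if name not in by_name:
            raise KeyError(f"no factor definition supplied for scored factor {name!r}")
        total += table.points_for(name, by_name[name].level_of(record))
    return total


@dataclass(frozen=True)
class ScoreRange:
    min_total: int
    max_total: int
    attainable: frozenset


def score_range(table: ScoreTable) -> ScoreRange:
    """Min/max total and the attainable set, by enumerating level combinations."""
    if not table.entries:
        raise ValueError("empty score table")
    per_factor = [table.factor_points(f) for f in table.factor_names]
    totals = {0}
    for pts in per_factor:
        totals = {t + p for t in totals for p in pts}
    return ScoreRange(
        min_total=sum(min(p) for p in per_factor),
        max_total=sum(max(p) for p in per_factor),
        attainable=frozenset(totals),
    )


# ---------------------------------------------------------------------------
# Prognostic groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrognosticGrouping:
    """Ordered, disjoint total-score intervals, each labelled."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        prev_hi = None
        for label, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"group {label}: empty interval [{lo}, {hi}]")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError("group intervals must be ordered and disjoint")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.intervals]

    def assign(self, total: int) -> str:
        for label, lo, hi in self.intervals:
            if lo <= total <= hi:
                return label
        raise ValueError(f"total score {total} falls outside every group interval")


#: Default stratification: 19-20 points (worst survival) -> A, 21-23 -> B,
#: 24 (best) -> C.
DEFAULT_GROUPING = PrognosticGrouping((("A", 19, 20), ("B", 21, 23), ("C", 24, 24)))


def assign_groups(totals, grouping: PrognosticGrouping = DEFAULT_GROUPING) -> list[str]:
    return [grouping.assign(int(t)) for t in totals]


def derive_grouping(
    cohort: Cohort,
    table: ScoreTable,
    factors: list[FactorDef],
    gap_pct: float = 10.0,
    t: float = 12.0,
) -> PrognosticGrouping:
    """Heuristic grouping: merge adjacent totals with similar survival.

    Computes the KM rate at ``t`` for each total present in the cohort and
    merges neighbouring totals whose rates differ by less than ``gap_pct``
    percentage points. A data-driven convenience with no claim of
    optimality — published groupings are usually designed by inspection.
    """
    totals = np.array([total_score(r, table, factors) for r in cohort])
    uniq = np.unique(totals)
    rates = []
    for u in uniq:
        recs = [r for r, tt in zip(cohort.records, totals) if tt == u]
        curve = km_estimate([r.survival_months for r in recs],
                            [r.death_observed for r in recs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates.append(100.0 * km_survival_at(curve, t))
    blocks: list[list[int]] = [[int(uniq[0])]]
    last_rate = rates[0]
    for u, rate in zip(uniq[1:], rates[1:]):
        if abs(rate - last_rate) < gap_pct:
            blocks[-1].append(int(u))
        else:
            blocks.append([int(u)])
        last_rate = rate
    rng = score_range(table)
    # stretch interval bounds so the grouping jointly covers the whole range
    starts = [rng.min_total] + [min(b) for b in blocks[1:]]
    ends = [s - 1 for s in starts[1:]] + [rng.max_total]
    intervals = tuple(
        (chr(ord("A") + i), lo, hi) for i, (lo, hi) in enumerate(zip(starts, ends))
    )
    return PrognosticGrouping(intervals)


@dataclass(frozen=True)
class GroupSurvival:
    """Per-group size and survival rate at the horizon, with overall log-rank p."""

    t: float
    n: dict          # label -> count
    rate: dict       # label -> percent at t (None for an empty group)
    p_logrank: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": g, "n": self.n[g], "rate_pct": self.rate[g],
        } for g in self.n])


def group_survival(
    cohort: Cohort,
    table: ScoreTable,
    factors: list[FactorDef],
    grouping: PrognosticGrouping = DEFAULT_GROUPING,
    t: float = 12.0,
) -> GroupSurvival:
    """KM rate at ``t`` per prognostic group plus the k-group log-rank p."""
    totals = [total_score(r, table, factors) for r in cohort]
    labels = assign_groups(totals, grouping)
    n, rate, groups_data = {}, {}, []
    for g in grouping.labels:
        recs = [r for r, lab in zip(cohort.records, labels) if lab == g]
        n[g] = len(recs)
        if not recs:
            rate[g] = None
            continue
        curve = km_estimate([r.survival_months for r in recs],
                            [r.death_observed for r in recs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate[g] = 100.0 * km_survival_at(curve, t)
        groups_data.append(([r.survival_months for r in recs],
                            [r.death_observed for r in recs]))
    p = logrank_test(groups_data).p if len(groups_data) >= 2 else None
    return GroupSurvival(t=t, n=n, rate=rate, p_logrank=p)


# ---------------------------------------------------------------------------
# Hold-out validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Group-by-group comparison of test-arm and validation-arm survival."""

    t: float
    groups: tuple[str, ...]
    n_validation: dict
    rate_test: dict
    rate_validation: dict
    difference: dict          # |test - validation| per group; None if not evaluable
    p_logrank_validation: float | None
    tolerance_pct: float
    reproducible: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": g,
            "n_validation": self.n_validation.get(g),
            "rate_test_pct": self.rate_test.get(g),
            "rate_validation_pct": self.rate_validation.get(g),
            "abs_difference_pct": self.difference.get(g),
        } for g in self.groups])

    def to_json(self) -> str:
        return json.dumps({
            "t_months": self.t,
            "per_group": self.to_frame().to_dict(orient="records"),
            "p_logrank_validation": self.p_logrank_validation,
            "tolerance_pct": self.tolerance_pct,
            "reproducible": self.reproducible,
        }, indent=2)


def compare_group_rates(
    rate_test: dict,
    rate_validation: dict,
    tolerance_pct: float = 10.0,
    t: float = 12.0,
    n_validation: dict | None = None,
    p_logrank_validation: float | None = None,
) -> ValidationReport:
    """Reproducibility check on given per-group rates (percent).

    The score is flagged reproducible when every evaluable per-group
    absolute difference is <= ``tolerance_pct`` percentage points.
    """
    groups = tuple(rate_test)
    diff = {}
    for g in groups:
        rt, rv = rate_test.get(g), rate_validation.get(g)
        diff[g] = abs(rt - rv) if rt is not None and rv is not None else None
    evaluable = [d for d in diff.values() if d is not None]
    reproducible = bool(evaluable) and all(d <= tolerance_pct for d in evaluable)
    return ValidationReport(
        t=t, groups=groups,
        n_validation=n_validation or {},
        rate_test=dict(rate_test), rate_validation=dict(rate_validation),
        difference=diff, p_logrank_validation=p_logrank_validation,
        tolerance_pct=tolerance_pct, reproducible=reproducible,
    )


def validate_score(
    validation: Cohort,
    table: ScoreTable,
    factors: list[FactorDef],
    test_result: GroupSurvival,
    grouping: PrognosticGrouping = DEFAULT_GROUPING,
    tolerance_pct: float = 10.0,
) -> ValidationReport:
    """Apply the frozen table and grouping to the hold-out arm.

    Nothing is re-estimated from the validation data: the score table is
    immutable and the grouping is the one built on the test arm. Reports
    per-group rates at the test result's horizon, the validation-arm
    log-rank p, and absolute differences vs the test arm.
    """
    val = group_survival(validation, table, factors, grouping, t=test_result.t)
    return compare_group_rates(
        rate_test=test_result.rate, rate_validation=val.rate,
        tolerance_pct=tolerance_pct, t=test_result.t,
        n_validation=val.n, p_logrank_validation=val.p_logrank,
    )
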