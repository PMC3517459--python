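"""Synthetic myeloma-SCC cohort generator.

Emulates the data-generating process behind the reference study so every
pipeline stage can be exercised without patient-level data: covariates are
drawn per-factor from configured unfavorable-level prevalences (optionally
with pairwise odds-ratio coupling), survival times are exponential with a
rate set either by a proportional-hazards linear predictor or by the
record's prognostic-group 12-month survival, and right censoring combines
uniform-accrual administrative censoring with exponential loss to
follow-up. Generation is a pure function of the config, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from . import reference
from .cohort import Cohort, PatientRecord, default_factors
from .score import DEFAULT_GROUPING, PrognosticGrouping, ScoreTable, total_score

SURVIVAL_MODES = ("proportional_hazards", "stratum", "ambulatory_sublevel")


@dataclass(frozen=True)
class PHParams:
    """Proportional-hazards survival: exponential baseline calibrated by its
    12-month survival, multiplied by each unfavorable factor's hazard ratio."""

    baseline_s12: float = 0.93
    hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.HAZARD_RATIOS))


@dataclass(frozen=True)
class StratumParams:
    """Stratum survival: exponential within prognostic group, rate
    -ln(S12)/12 from the group's true 12-month survival."""

    group_s12: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.GROUP_S12["test"]))
    score_table: ScoreTable | None = None          # None -> shipped reference table
    grouping: PrognosticGrouping = DEFAULT_GROUPING


@dataclass(frozen=True)
class CensoringConfig:
    """Right censoring: administrative (uniform accrual over
    ``accrual_months`` with a fixed analysis date, so time on study is
    uniform) plus independent exponential loss to follow-up."""

    enabled: bool = True
    accrual_months: float = 228.0
    ltfu_rate_per_month: float = 0.009


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = reference.ARM_N
    seed: int = 1234
    prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.POOLED_PREVALENCES))
    #: pairwise odds ratios coupling factors, keys = frozenset({f1, f2})
    dependence: Mapping[frozenset, float] = field(default_factory=dict)
    survival_mode: str = "stratum"
    ph_params: PHParams = field(default_factory=PHParams)
    stratum_params: StratumParams = field(default_factory=StratumParams)
    censoring: CensoringConfig = field(default_factory=CensoringConfig)
    #: P(walks with aid | ambulatory), for the sub-level merge check
    ambulatory_split: float = 0.5
    sublevel_s12: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.AMBULATORY_SUBLEVEL_S12))
    label: str = "synthetic"

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.survival_mode not in SURVIVAL_MODES:
            raise ValueError(f"survival_mode must be one of {SURVIVAL_MODES}")
        for k, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {k} must be in [0,1], got {p}")
        if not 0.0 <= self.ambulatory_split <= 1.0:
            raise ValueError("ambulatory_split must be in [0,1]")
        if not 0.0 < self.ph_params.baseline_s12 <= 1.0:
            raise ValueError("baseline_s12 must be in (0,1]")
        for k, hr in self.ph_params.hazard_ratios.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio of {k} must be > 0, got {hr}")
        for k, s in self.stratum_params.group_s12.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"group {k}: S12 must be in (0,1], got {s}")
        for k, s in self.sublevel_s12.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"sub-level {k}: S12 must be in (0,1], got {s}")
        for pair, orr in self.dependence.items():
            if len(pair) != 2 or orr <= 0:
                raise ValueError(f"dependence entry {pair}: need a factor pair and OR > 0")
        if self.censoring.accrual_months <= 0 or self.censoring.ltfu_rate_per_month < 0:
            raise ValueError("invalid censoring configuration")


def reference_calibration(arm: str = "test", seed: int = 1234) -> GeneratorConfig:
    """Config pre-filled with the reference study's printed numbers.

    Arm-specific unfavorable-level prevalences (108-patient margins), the
    published hazard ratios for proportional-hazards mode, and the arm's
    prognostic-group 12-month survivals for stratum mode.
    """
    if arm not in ("test", "validation"):
        raise ValueError("arm must be 'test' or 'validation'")
    prev = {k: c / reference.ARM_N for k, c in reference.UNFAVORABLE_COUNTS[arm].items()}
    return GeneratorConfig(
        n=reference.ARM_N,
        seed=seed,
        prevalences=prev,
        stratum_params=StratumParams(group_s12=dict(reference.GROUP_S12[arm])),
        label=f"synthetic/{arm}",
    )


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------

def _coupled_joint(names, prevalences, dependence):
    """Joint distribution over coupled binary factors matching the marginal
    prevalences with the requested pairwise odds ratios.

    Built sequentially: each factor's conditional odds given its coupled
    predecessors are base_odds * prod(OR^x); the base odds are solved so the
    marginal comes out exactly. With three or more mutually coupled factors
    the pairwise ORs are matched conditionally (an approximation to the
    marginal ORs), which is adequate for stress-testing the pipeline.
    """
    joint = {(): 1.0}
    for j, name in enumerate(names):
        p_j = prevalences[name]
        partners = [(i, dependence[frozenset({name, names[i]})])
                    for i in range(j)
                    if frozenset({name, names[i]}) in dependence]

        def marginal(base_odds):
            tot = 0.0
            for combo, prob in joint.items():
                odds = base_odds * math.prod(orr for i, orr in partners if combo[i])
                tot += prob * odds / (1.0 + odds)
            return tot - p_j

        if p_j <= 0.0:
            base = 0.0
        elif p_j >= 1.0:
            base = math.inf
        elif not partners:
            base = p_j / (1.0 - p_j)
        else:
            base = brentq(marginal, 1e-12, 1e12)
        new_joint = {}
        for combo, prob in joint.items():
            if base == 0.0:
                p_cond = 0.0
            elif base == math.inf:
                p_cond = 1.0
            else:
                odds = base * math.prod(orr for i, orr in partners if combo[i])
                p_cond = odds / (1.0 + odds)
            new_joint[combo + (1,)] = prob * p_cond
            new_joint[combo + (0,)] = prob * (1.0 - p_cond)
        joint = new_joint
    return joint


def _draw_indicators(rng, config, factor_names):
    """n x k matrix of unfavorable-level indicators."""
    n = config.n
    coupled = sorted({f for pair in config.dependence for f in pair})
    out = {}
    if coupled:
        joint = _coupled_joint(coupled, config.prevalences, config.dependence)
        combos = list(joint)
        probs = np.array([joint[c] for c in combos])
        probs = probs / probs.sum()
        picks = rng.choice(len(combos), size=n, p=probs)
        for idx, name in enumerate(coupled):
            out[name] = np.array([combos[k][idx] for k in picks], dtype=int)
    for name in factor_names:
        if name not in out:
            out[name] = (rng.random(n) < config.prevalences.get(name, 0.0)).astype(int)
    return out


def _records_from_indicators(rng, config, ind) -> list[dict]:
    """Fill concrete in-range field values consistent with each indicator.

    The continuous fields carry no survival effect; they only need to land
    on the right side of their dichotomy cut-point.
    """
    n = config.n
    rows = []
    with_aid = rng.random(n) < config.ambulatory_split
    for i in range(n):
        amb_unfav = ind["ambulatory"][i]
        rows.append({
            "patient_id": f"P{i + 1:05d}",
            "age_years": int(rng.integers(64, 86)) if ind["age"][i] else int(rng.integers(30, 64)),
            "gender": "female" if ind["gender"][i] else "male",
            "ecog_ps": int(rng.integers(3, 5)) if ind["ecog"][i] else int(rng.integers(1, 3)),
            "n_involved_vertebrae": int(rng.integers(3, 9)) if ind["vertebrae"][i]
            else int(rng.integers(1, 3)),
            "ambulatory_status": "not_ambulatory" if amb_unfav
            else ("ambulatory_with_aid" if with_aid[i] else "ambulatory_without_aid"),
            "other_bone_lesions": bool(ind["bone_lesions"][i]),
            "extraosseous_lesions": bool(ind["extraosseous"][i]),
            "interval_dx_to_rt_months": float(rng.uniform(15.01, 120.0)) if ind["interval"][i]
            else float(rng.uniform(0.0, 15.0)),
            "motor_deficit_days": int(rng.integers(1, 15)) if ind["motor_deficit_time"][i]
            else int(rng.integers(15, 61)),
            "radiation_regimen": "short_course" if ind["regimen"][i] else "longer_course",
        })
    return rows


def _rate_from_s12(s12: float) -> float:
    """Exponential hazard (per month) with the given 12-month survival."""
    if s12 >= 1.0:
        return 0.0
    return -math.log(s12) / 12.0


def _survival_rates(config, rows, ind) -> np.ndarray:
    """Per-record exponential hazard according to the survival mode."""
    n = config.n
    if config.survival_mode == "proportional_hazards":
        rate0 = _rate_from_s12(config.ph_params.baseline_s12)
        rates = np.full(n, rate0)
        for name, hr in config.ph_params.hazard_ratios.items():
            rates *= np.power(hr, ind[name])
        return rates
    if config.survival_mode == "ambulatory_sublevel":
        return np.array([_rate_from_s12(config.sublevel_s12[r["ambulatory_status"]])
                         for r in rows])
    # stratum mode: group membership via the frozen score table
    table = config.stratum_params.score_table or reference.reference_score_table()
    grouping = config.stratum_params.grouping
    factors = default_factors()
    by_name = {f.name: f for f in factors}
    sel = [by_name[name] for name in table.factor_names]
    rates = np.empty(n)
    for i, row in enumerate(rows):
        rec = PatientRecord(survival_months=0.0, death_observed=False, **row)
        group = grouping.assign(total_score(rec, table, sel))
        rates[i] = _rate_from_s12(config.stratum_params.group_s12[group])
    return rates


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a synthetic cohort; byte-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    factor_names = list(reference.POOLED_PREVALENCES)
    ind = _draw_indicators(rng, config, factor_names)
    rows = _records_from_indicators(rng, config, ind)
    rates = _survival_rates(config, rows, ind)

    with np.errstate(divide="ignore"):
        scale = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0), np.inf)
    death_time = np.where(rates > 0,
                          rng.exponential(np.where(np.isfinite(scale), scale, 1.0)),
                          np.inf)
    if config.censoring.enabled:
        admin = rng.uniform(0.0, config.censoring.accrual_months, size=config.n)
        if config.censoring.ltfu_rate_per_month > 0:
            ltfu = rng.exponential(1.0 / config.censoring.ltfu_rate_per_month, size=config.n)
        else:
            ltfu = np.full(config.n, np.inf)
        censor_time = np.minimum(admin, ltfu)
    else:
        censor_time = np.full(config.n, np.inf)
        if not np.all(np.isfinite(death_time)):
            raise ValueError("infinite survival times require censoring to be enabled")

    records = []
    for i, row in enumerate(rows):
        event = bool(death_time[i] <= censor_time[i])
        t_obs = float(death_time[i] if event else censor_time[i])
        records.append(PatientRecord(survival_months=t_obs, death_observed=event, **row))
    return Cohort(records, label=config.label)


# ---------------------------------------------------------------------------
# Deterministic fixture
# ---------------------------------------------------------------------------

#: Joint (ECOG 3-4, not ambulatory, bone lesions) cell counts of the fixture,
#: chosen so that scoring with the shipped table yields prognostic groups of
#: exactly 26 / 49 / 33 patients while hitting the reference test-arm margins
#: (33 ECOG 3-4, 27 not ambulatory, 63 with other bone lesions, n = 108).
_FIXTURE_CELLS = {
    # (ecog_unfav, not_ambulatory, bone_lesions): count
    (1, 1, 1): 17, (1, 1, 0): 9,
    (1, 0, 1): 4, (1, 0, 0): 3,
    (0, 1, 1): 1, (0, 1, 0): 0,
    (0, 0, 1): 41, (0, 0, 0): 33,
}

_FIXTURE_SEED = 987654321


def fixture_test_cohort() -> Cohort:
    """A fixed 108-record test-style cohort with the reference joint structure.

    The three scored factors follow the cell counts above (so the worst
    prognostic group has exactly 26 members and the best 33); the remaining
    factors are assigned to match the reference test-arm margins; survival
    is drawn once, in stratum mode, from a fixed internal seed.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    cells = []
    for cell, count in _FIXTURE_CELLS.items():
        cells.extend([cell] * count)
    order = rng.permutation(len(cells))
    cells = [cells[i] for i in order]
    n = len(cells)

    config = reference_calibration("test", seed=_FIXTURE_SEED)

    def margin_vector(count):
        v = np.zeros(n, dtype=int)
        v[rng.choice(n, size=count, replace=False)] = 1
        return v

    counts = reference.UNFAVORABLE_COUNTS["test"]
    ind = {
        "ecog": np.array([c[0] for c in cells]),
        "ambulatory": np.array([c[1] for c in cells]),
        "bone_lesions": np.array([c[2] for c in cells]),
        "age": margin_vector(counts["age"]),
        "gender": margin_vector(counts["gender"]),
        "vertebrae": margin_vector(counts["vertebrae"]),
        "extraosseous": margin_vector(counts["extraosseous"]),
        "interval": margin_vector(counts["interval"]),
        "motor_deficit_time": margin_vector(counts["motor_deficit_time"]),
        "regimen": margin_vector(counts["regimen"]),
    }
    rows = _records_from_indicators(rng, config, ind)
    rates = _survival_rates(config, rows, ind)
    death_time = rng.exponential(1.0 / rates)
    admin = rng.uniform(0.0, config.censoring.accrual_months, size=n)
    ltfu = rng.exponential(1.0 / config.censoring.ltfu_rate_per_month, size=n)
    censor_time = np.minimum(admin, ltfu)
    records = []
    for i, row in enumerate(rows):
        event = bool(death_time[i] <= censor_time[i])
        t_obs = float(death_time[i] if event else censor_time[i])
        records.append(PatientRecord(survival_months=t_obs, death_observed=event, **row))
    return Cohort(records, label="fixture/test")
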