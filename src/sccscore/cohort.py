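"""Patient-level cohort model for irradiated spinal cord compression (SCC).

One record per patient: the nine pre-treatment factors investigated for
myeloma SCC (age, gender, ECOG performance status, number of involved
vertebrae, ambulatory status, other bone lesions, extraosseous lesions,
interval from myeloma diagnosis to radiotherapy, time developing motor
deficits), the radiation regimen, and a right-censored survival outcome
(months from the start of radiotherapy; death indicator).

The module also provides the factor dichotomization used throughout the
scoring pipeline, delimited-text I/O, the alternating odd/even test /
validation split, the ambulatory sub-level merge check, and a
characteristics table comparing the two arms factor by factor with a
chi-square test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up

GENDERS = ("female", "male")
AMBULATORY_LEVELS = ("not_ambulatory", "ambulatory_with_aid", "ambulatory_without_aid")
REGIMENS = ("short_course", "longer_course")


class CohortFormatError(ValueError):
    """A cohort file is structurally unreadable (e.g. missing columns)."""


class CohortValidationError(ValueError):
    """A field value violates the patient-record invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """A single SCC patient: covariates plus right-censored survival.

    ``survival_months`` counts from the start of radiotherapy to death
    (``death_observed=True``) or last follow-up (censored).
    """

    patient_id: str
    age_years: int
    gender: str
    ecog_ps: int
    n_involved_vertebrae: int
    ambulatory_status: str
    other_bone_lesions: bool
    extraosseous_lesions: bool
    interval_dx_to_rt_months: float
    motor_deficit_days: int
    radiation_regimen: str
    survival_months: float
    death_observed: bool

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise CohortValidationError(f"age_years must be positive, got {self.age_years}")
        if self.gender not in GENDERS:
            raise CohortValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.ecog_ps not in (1, 2, 3, 4):
            raise CohortValidationError(f"ecog_ps must be in 1..4, got {self.ecog_ps}")
        if self.n_involved_vertebrae <= 0:
            raise CohortValidationError(
                f"n_involved_vertebrae must be positive, got {self.n_involved_vertebrae}"
            )
        if self.ambulatory_status not in AMBULATORY_LEVELS:
            raise CohortValidationError(
                f"ambulatory_status must be one of {AMBULATORY_LEVELS}, "
                f"got {self.ambulatory_status!r}"
            )
        if self.interval_dx_to_rt_months < 0:
            raise CohortValidationError(
                f"interval_dx_to_rt_months must be >= 0, got {self.interval_dx_to_rt_months}"
            )
        if self.motor_deficit_days <= 0:
            raise CohortValidationError(
                f"motor_deficit_days must be positive, got {self.motor_deficit_days}"
            )
        if self.radiation_regimen not in REGIMENS:
            raise CohortValidationError(
                f"radiation_regimen must be one of {REGIMENS}, got {self.radiation_regimen!r}"
            )
        if self.survival_months < 0:
            raise CohortValidationError(
                f"survival_months must be >= 0, got {self.survival_months}"
            )

    @property
    def ambulatory(self) -> bool:
        """Pooled ambulatory level: walking with or without aid."""
        return self.ambulatory_status in (
            "ambulatory_with_aid",
            "ambulatory_without_aid",
        )


@dataclass(frozen=True)
class FactorDef:
    """A dichotomized prognostic factor.

    ``extractor`` maps a record to one of exactly two level labels;
    ``unfavorable_level`` is the level coded 1 in regression so hazard
    ratios come out >= 1-directed for the worse level.
    """

    name: str
    extractor: Callable[[PatientRecord], str]
    favorable_level: str
    unfavorable_level: str

    def __post_init__(self) -> None:
        if self.favorable_level == self.unfavorable_level:
            raise ValueError(f"factor {self.name}: levels must differ")

    @property
    def levels(self) -> tuple[str, str]:
        return (self.favorable_level, self.unfavorable_level)

    def level_of(self, record: PatientRecord) -> str:
        level = self.extractor(record)
        if level not in self.levels:
            raise ValueError(
                f"factor {self.name}: extractor produced {level!r}, "
                f"expected one of {self.levels}"
            )
        return level

    def indicator(self, record: PatientRecord) -> int:
        """1 if the record sits at the unfavorable level, else 0."""
        return int(self.level_of(record) == self.unfavorable_level)


@dataclass
class Cohort:
    """An ordered list of patients; order is accrual order (used for splitting)."""

    records: list[PatientRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.survival_months for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.death_observed for r in self.records], dtype=bool)

    def subset(self, mask: Sequence[bool], label: str = "") -> "Cohort":
        recs = [r for r, m in zip(self.records, mask) if m]
        return Cohort(recs, label or self.label)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(PatientRecord)]
        rows = [{c: getattr(r, c) for c in cols} for r in self.records]
        df = pd.DataFrame(rows, columns=cols)
        df["other_bone_lesions"] = df["other_bone_lesions"].astype(int)
        df["extraosseous_lesions"] = df["extraosseous_lesions"].astype(int)
        df["death_observed"] = df["death_observed"].astype(int)
        return df


def default_factors(
    age_cut: int = 63,
    vertebrae_cut: int = 2,
    interval_cut_months: float = 15.0,
    motor_deficit_cut_days: int = 14,
) -> list[FactorDef]:
    """The nine pre-treatment factors plus the radiation regimen.

    Cut-points default to the dichotomies of the motivating myeloma SCC
    study: age <=63 vs >=64 (cohort median 63), ECOG 1-2 vs 3-4,
    1-2 vs >=3 involved vertebrae, ambulatory (with or without aid,
    pooled) vs not, other bone lesions and extraosseous lesions no/yes,
    interval from myeloma diagnosis to radiotherapy <=15 vs >15 months,
    motor deficits developing over 1-14 vs >14 days (slower development
    is favorable), and short- vs longer-course radiotherapy.
    """
    a_lo, a_hi = f"<={age_cut}", f">={age_cut + 1}"
    v_lo, v_hi = ("1-2" if vertebrae_cut == 2 else f"1-{vertebrae_cut}"), f">={vertebrae_cut + 1}"
    i_lo, i_hi = f"<={interval_cut_months:g}", f">{interval_cut_months:g}"
    m_lo, m_hi = f"1-{motor_deficit_cut_days}", f">{motor_deficit_cut_days}"
    return [
        FactorDef("age", lambda r, c=age_cut, lo=a_lo, hi=a_hi: lo if r.age_years <= c else hi,
                  favorable_level=a_lo, unfavorable_level=a_hi),
        FactorDef("gender", lambda r: r.gender,
                  favorable_level="male", unfavorable_level="female"),
        FactorDef("ecog", lambda r: "1-2" if r.ecog_ps <= 2 else "3-4",
                  favorable_level="1-2", unfavorable_level="3-4"),
        FactorDef("vertebrae",
                  lambda r, c=vertebrae_cut, lo=v_lo, hi=v_hi:
                  lo if r.n_involved_vertebrae <= c else hi,
                  favorable_level=v_lo, unfavorable_level=v_hi),
        FactorDef("ambulatory",
                  lambda r: "ambulatory" if r.ambulatory else "not ambulatory",
                  favorable_level="ambulatory", unfavorable_level="not ambulatory"),
        FactorDef("bone_lesions", lambda r: "yes" if r.other_bone_lesions else "no",
                  favorable_level="no", unfavorable_level="yes"),
        FactorDef("extraosseous", lambda r: "yes" if r.extraosseous_lesions else "no",
                  favorable_level="no", unfavorable_level="yes"),
        FactorDef("interval",
                  lambda r, c=interval_cut_months, lo=i_lo, hi=i_hi:
                  lo if r.interval_dx_to_rt_months <= c else hi,
                  favorable_level=i_lo, unfavorable_level=i_hi),
        FactorDef("motor_deficit_time",
                  lambda r, c=motor_deficit_cut_days, lo=m_lo, hi=m_hi:
                  lo if r.motor_deficit_days <= c else hi,
                  favorable_level=m_hi, unfavorable_level=m_lo),
        FactorDef("regimen",
                  lambda r: "short course" if r.radiation_regimen == "short_course"
                  else "longer course",
                  favorable_level="longer course", unfavorable_level="short course"),
    ]


def dichotomize(record: PatientRecord, factors: Sequence[FactorDef]) -> dict[str, str]:
    """Map a record to its level label under every factor. Deterministic and total."""
    return {f.name: f.level_of(record) for f in factors}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = [f.name for f in dc_fields(PatientRecord)]
_BOOL_COLUMNS = ("other_bone_lesions", "extraosseous_lesions", "death_observed")
_INT_COLUMNS = ("age_years", "ecog_ps", "n_involved_vertebrae", "motor_deficit_days")
_FLOAT_COLUMNS = ("interval_dx_to_rt_months", "survival_months")


def _parse_bool(raw: str, col: str, row: int) -> bool:
    if raw in ("1", "true", "True"):
        return True
    if raw in ("0", "false", "False"):
        return False
    raise CohortValidationError(f"row {row}: field {col}: cannot parse {raw!r} as 0/1")


def read_cohort(path: str | Path, delimiter: str = ",", label: str | None = None) -> Cohort:
    """Read a delimited cohort file (one row per patient, header required).

    Rows violating a record invariant are rejected with their 1-based data
    row index; a missing mandatory column raises :class:`CohortFormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing mandatory columns {missing}")
    records = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        kwargs: dict = {}
        for col in _COLUMNS:
            value = getattr(raw, col)
            try:
                if col in _BOOL_COLUMNS:
                    kwargs[col] = _parse_bool(value, col, i)
                elif col in _INT_COLUMNS:
                    kwargs[col] = int(value)
                elif col in _FLOAT_COLUMNS:
                    kwargs[col] = float(value)
                else:
                    kwargs[col] = value
            except (TypeError, ValueError) as exc:
                if isinstance(exc, CohortValidationError):
                    raise
                raise CohortValidationError(
                    f"row {i}: field {col}: cannot parse {value!r}"
                ) from exc
        try:
            records.append(PatientRecord(**kwargs))
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from exc
    return Cohort(records, label if label is not None else path.stem)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort so that :func:`read_cohort` round-trips it field for field."""
    path = Path(path)
    df = cohort.to_frame()
    # repr-format floats so fractional months survive the round trip exactly
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].map(repr)
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Splitting and arm comparison
# ---------------------------------------------------------------------------

def alternate_split(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Alternating assignment by accrual order.

    Patients at odd 1-based positions (1st, 3rd, ...) form the test arm,
    even positions the validation arm; together they partition the cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    test = Cohort(cohort.records[0::2], label=f"{cohort.label}/test")
    validation = Cohort(cohort.records[1::2], label=f"{cohort.label}/validation")
    return test, validation


@dataclass(frozen=True)
class AmbulatoryMergeReport:
    """Survival-equivalence check between the two ambulatory sub-levels."""

    rate_without_aid: float | None
    rate_with_aid: float | None
    p_logrank: float | None
    merged: bool
    evaluable: bool
    note: str = ""


def merge_ambulatory_check(cohort: Cohort, t: float = 12.0) -> AmbulatoryMergeReport:
    """Check whether walking with vs without aid can be pooled as "ambulatory".

    Compares the Kaplan-Meier survival at ``t`` months between the two
    ambulatory sub-levels and reports a two-group log-rank p-value. The
    pipeline always proceeds with the pooled level; the report documents
    whether the data support that merge. When a sub-level is absent the
    check is not evaluable and the merge still proceeds.
    """
    from .survival import km_estimate, km_survival_at, logrank_test

    without = [r for r in cohort if r.ambulatory_status == "ambulatory_without_aid"]
    withaid = [r for r in cohort if r.ambulatory_status == "ambulatory_with_aid"]
    if not without or not withaid:
        return AmbulatoryMergeReport(
            rate_without_aid=None, rate_with_aid=None, p_logrank=None,
            merged=True, evaluable=False,
            note="an ambulatory sub-level is absent; check not evaluable",
        )

    def _rate(recs):
        curve = km_estimate([r.survival_months for r in recs],
                            [r.death_observed for r in recs])
        return 100.0 * km_survival_at(curve, t)

    lr = logrank_test([
        ([r.survival_months for r in without], [r.death_observed for r in without]),
        ([r.survival_months for r in withaid], [r.death_observed for r in withaid]),
    ])
    return AmbulatoryMergeReport(
        rate_without_aid=_rate(without), rate_with_aid=_rate(withaid),
        p_logrank=lr.p, merged=True, evaluable=True,
    )


def characteristics_table(
    test: Cohort,
    validation: Cohort,
    factors: Sequence[FactorDef],
    yates_correction: bool = False,
) -> pd.DataFrame:
    """Per-factor level counts and percentages in each arm with a chi-square p.

    Pearson chi-square on the 2x2 factor-by-arm table (Yates continuity
    correction togglable, off by default). Percentages are rounded half-up
    for display; the underlying counts are exact. A factor with a level
    empty in both arms gets ``NaN`` for chi2 and p (not evaluable).
    """
    if len(test) == 0 or len(validation) == 0:
        raise ValueError("both arms must be non-empty")
    rows = []
    for f in factors:
        counts = np.zeros((2, 2), dtype=int)  # level x arm
        for j, arm in enumerate((test, validation)):
            for r in arm:
                counts[f.levels.index(f.level_of(r)), j] += 1
        if (counts.sum(axis=1) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates_correction)
        for i, level in enumerate(f.levels):
            rows.append({
                "factor": f.name,
                "level": level,
                "test_n": int(counts[i, 0]),
                "test_pct": round_half_up(100.0 * counts[i, 0] / len(test)),
                "validation_n": int(counts[i, 1]),
                "validation_pct": round_half_up(100.0 * counts[i, 1] / len(validation)),
                "chi2": float(chi2) if np.isfinite(chi2) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
            })
    return pd.DataFrame(rows)


def characteristics_to_json(table: pd.DataFrame) -> str:
    """JSON mirror of the characteristics table, one object per factor level."""
    recs = table.to_dict(orient="records")
    for r in recs:
        for k, v in r.items():
            if isinstance(v, float) and not np.isfinite(v):
                r[k] = None
    return json.dumps(recs, indent=2)
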