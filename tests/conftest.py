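import pytest

from sccscore import Cohort, PatientRecord, default_factors, reference_score_table

_DEFAULTS = dict(
    patient_id="P1",
    age_years=60,
    gender="male",
    ecog_ps=1,
    n_involved_vertebrae=2,
    ambulatory_status="ambulatory_without_aid",
    other_bone_lesions=False,
    extraosseous_lesions=False,
    interval_dx_to_rt_months=10.0,
    motor_deficit_days=20,
    radiation_regimen="longer_course",
    survival_months=24.0,
    death_observed=False,
)


@pytest.fixture
def make_record():
    """Factory for a valid patient record with selective field overrides."""

    def _make(**overrides):
        return PatientRecord(**{**_DEFAULTS, **overrides})

    return _make


@pytest.fixture
def make_cohort(make_record):
    """Cohort from per-record override dicts (patient ids auto-assigned)."""

    def _make(rows, label="t"):
        recs = [make_record(patient_id=f"P{i+1}", **row) for i, row in enumerate(rows)]
        return Cohort(recs, label)

    return _make


@pytest.fixture(scope="session")
def ref_table():
    return reference_score_table()


@pytest.fixture(scope="session")
def scored_factors():
    table = reference_score_table()
    return [f for f in default_factors() if f.name in table.factor_names]
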