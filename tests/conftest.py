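import datetime

import pytest

from asthmafinder.emr import (
    BillingEntry,
    Cohort,
    EncounterDiagnosis,
    HealthCondition,
    Patient,
    Prescription,
)

REF = datetime.date(2015, 6, 30)


def _birth(age: int) -> datetime.date:
    # mid-January birthday: the anniversary has passed by 30 June, so
    # completed age at REF equals `age` exactly
    return datetime.date(REF.year - age, 1, 15)


def _rx(pid: str, n: int = 1) -> list[Prescription]:
    return [
        Prescription(pid, datetime.date(2015, 3, 1 + i), "Salbutamol", "R03AC02")
        for i in range(n)
    ]


@pytest.fixture
def rule_arm_cohort() -> tuple[Cohort, dict[str, bool]]:
    """Seven hand-built patients, one per arm of the combination rule."""
    d = datetime.date(2015, 2, 1)
    patients = [
        Patient("two_scripts", _birth(5)),
        Patient("one_script_billing", _birth(8)),
        Patient("one_script_encounter", _birth(8)),
        Patient("one_script_condition", _birth(8)),
        Patient("exclusion_only", _birth(10)),
        Patient("diagnosis_only", _birth(7)),
        Patient("age_gate", _birth(18)),
    ]
    cohort = Cohort(
        patients=patients,
        billing=[
            BillingEntry("one_script_billing", d, "493"),
            BillingEntry("diagnosis_only", d, "493.90"),
            BillingEntry("age_gate", d, "493"),
        ],
        encounters=[
            EncounterDiagnosis("one_script_encounter", d, diagnosis_text="asthma"),
            EncounterDiagnosis("exclusion_only", d, diagnosis_text="asthma query"),
            EncounterDiagnosis("diagnosis_only", d, diagnosis_text="Asthma"),
            EncounterDiagnosis("age_gate", d, diagnosis_text="asthma"),
        ],
        conditions=[
            HealthCondition(
                "one_script_condition", d, condition_text="Asthmatic bronchitis"
            ),
        ],
        prescriptions=(
            _rx("two_scripts", 2)
            + _rx("one_script_billing", 1)
            + _rx("one_script_encounter", 1)
            + _rx("one_script_condition", 1)
            + _rx("age_gate", 5)
        ),
        reference_date=REF,
    ).validate()
    expected = {
        "two_scripts": True,
        "one_script_billing": True,
        "one_script_encounter": True,
        "one_script_condition": True,
        "exclusion_only": False,
        "diagnosis_only": False,
        "age_gate": False,
    }
    return cohort, expected
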