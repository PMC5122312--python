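"""Relational EMR data model mirroring a CPCSSN-style extract.

A cohort is five linked tables — patient demographics plus billing
diagnoses, encounter diagnoses, health-condition (problem-list) entries
and prescribed medications — exchanged as UTF-8 comma-separated text with
a header row and ISO-8601 dates.  Only the columns the asthma case
definition reads are modelled; the real CPCSSN schema is much richer.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Extraction cut-off used as the default age-reference date.
DEFAULT_REFERENCE_DATE = datetime.date(2015, 6, 30)

#: WHO ATC code shape: letter, two digits, two letters, two digits.
ATC_SHAPE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: Canonical table file names for a cohort directory.
TABLE_FILES = {
    "patients": "patient.csv",
    "billing": "billing.csv",
    "encounters": "encounter_diagnosis.csv",
    "conditions": "health_condition.csv",
    "prescriptions": "medication.csv",
}


class CohortError(ValueError):
    """Raised when an extract violates the data model."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: Optional[datetime.date]
    sex: str = "U"  # M, F or U (other/unknown)


@dataclass(frozen=True)
class BillingEntry:
    patient_id: str
    date: datetime.date
    diagnosis_code: str


@dataclass(frozen=True)
class EncounterDiagnosis:
    patient_id: str
    date: datetime.date
    diagnosis_code: str = ""
    diagnosis_text: str = ""


@dataclass(frozen=True)
class HealthCondition:
    patient_id: str
    date_onset: Optional[datetime.date] = None
    condition_code: str = ""
    condition_text: str = ""


@dataclass(frozen=True)
class Prescription:
    patient_id: str
    date: datetime.date
    drug_name: str = ""
    atc_code: str = ""


@dataclass
class Cohort:
    """Linked EMR tables for one patient population.

    Invariants (enforced by :meth:`validate`): patient ids are unique,
    every event row points at a known patient, birth dates do not fall
    after ``reference_date``, non-empty ATC codes have the standard
    7-character shape, and code/text row types carry at least one
    non-empty payload field.
    """

    patients: list[Patient] = field(default_factory=list)
    billing: list[BillingEntry] = field(default_factory=list)
    encounters: list[EncounterDiagnosis] = field(default_factory=list)
    conditions: list[HealthCondition] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    reference_date: datetime.date = DEFAULT_REFERENCE_DATE

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def __len__(self) -> int:
        return len(self.patients)

    def validate(self) -> "Cohort":
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise CohortError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            if p.birth_date is not None and p.birth_date > self.reference_date:
                raise CohortError(
                    f"patient {p.patient_id!r}: birth_date {p.birth_date} is after "
                    f"reference_date {self.reference_date}"
                )
        for table_name, rows in (
            ("billing", self.billing),
            ("encounter_diagnosis", self.encounters),
            ("health_condition", self.conditions),
            ("medication", self.prescriptions),
        ):
            for i, row in enumerate(rows):
                if row.patient_id not in seen:
                    raise CohortError(
                        f"{table_name} row {i + 1}: unknown patient_id {row.patient_id!r}"
                    )
        for i, b in enumerate(self.billing):
            if not b.diagnosis_code.strip():
                raise CohortError(f"billing row {i + 1}: empty diagnosis_code")
        for i, e in enumerate(self.encounters):
            if not (e.diagnosis_code.strip() or e.diagnosis_text.strip()):
                raise CohortError(
                    f"encounter_diagnosis row {i + 1}: both code and text empty"
                )
        for i, c in enumerate(self.conditions):
            if not (c.condition_code.strip() or c.condition_text.strip()):
                raise CohortError(
                    f"health_condition row {i + 1}: both code and text empty"
                )
        for i, rx in enumerate(self.prescriptions):
            code = rx.atc_code.strip().upper()
            if code and not ATC_SHAPE.match(code):
                raise CohortError(
                    f"medication row {i + 1}: malformed ATC code {rx.atc_code!r}"
                )
        return self


def age_in_years(
    birth_date: datetime.date, reference_date: datetime.date = DEFAULT_REFERENCE_DATE
) -> int:
    """Completed years of age at ``reference_date``.

    The count decrements by one when the reference date falls before the
    birthday anniversary within the reference year, so a child born
    2014-07-01 is 0 on 2015-06-30 and 1 on 2015-07-01.
    """
    if birth_date > reference_date:
        raise ValueError(
            f"birth_date {birth_date} is after reference_date {reference_date}"
        )
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# Delimited-text IO


def _parse_date(value: str, *, table: str, row: int, column: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise CohortError(
            f"{table} row {row}: malformed {column} {value!r} (expected ISO-8601)"
        ) from exc


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortError(f"missing table file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortError(f"{path.name}: missing column(s) {missing}")
    return df


def load_cohort(
    source: Path | str | Mapping[str, Path | str],
    reference_date: datetime.date = DEFAULT_REFERENCE_DATE,
) -> Cohort:
    """Read a cohort from its five CSV tables.

    ``source`` is either a directory holding the canonical file names
    (see :data:`TABLE_FILES`) or a mapping from table key to path.  Rows
    are validated as they are read; an orphan row, a duplicate patient id
    or a malformed event date is fatal with the offending row number.
    An empty or unparseable birth date yields a patient with
    ``birth_date=None`` (excluded from classification later) and a
    logged warning rather than an error.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {key: base / name for key, name in TABLE_FILES.items()}
    else:
        paths = {key: Path(p) for key, p in source.items()}

    pdf = _read_table(paths["patients"], ["patient_id", "birth_date", "sex"])
    patients: list[Patient] = []
    for i, rec in enumerate(pdf.itertuples(index=False), start=1):
        raw = rec.birth_date.strip()
        birth: Optional[datetime.date]
        if not raw:
            birth = None
            logger.warning("patient row %d (%s): missing birth_date", i, rec.patient_id)
        else:
            try:
                birth = datetime.date.fromisoformat(raw)
            except ValueError:
                birth = None
                logger.warning(
                    "patient row %d (%s): unparseable birth_date %r",
                    i,
                    rec.patient_id,
                    raw,
                )
        patients.append(Patient(rec.patient_id, birth, rec.sex or "U"))

    bdf = _read_table(paths["billing"], ["patient_id", "date", "diagnosis_code"])
    billing = [
        BillingEntry(
            r.patient_id,
            _parse_date(r.date, table="billing", row=i, column="date"),
            r.diagnosis_code,
        )
        for i, r in enumerate(bdf.itertuples(index=False), start=1)
    ]

    edf = _read_table(
        paths["encounters"], ["patient_id", "date", "diagnosis_code", "diagnosis_text"]
    )
    encounters = [
        EncounterDiagnosis(
            r.patient_id,
            _parse_date(r.date, table="encounter_diagnosis", row=i, column="date"),
            r.diagnosis_code,
            r.diagnosis_text,
        )
        for i, r in enumerate(edf.itertuples(index=False), start=1)
    ]

    cdf = _read_table(
        paths["conditions"],
        ["patient_id", "date_onset", "condition_code", "condition_text"],
    )
    conditions = [
        HealthCondition(
            r.patient_id,
            (
                _parse_date(
                    r.date_onset, table="health_condition", row=i, column="date_onset"
                )
                if r.date_onset.strip()
                else None
            ),
            r.condition_code,
            r.condition_text,
        )
        for i, r in enumerate(cdf.itertuples(index=False), start=1)
    ]

    mdf = _read_table(
        paths["prescriptions"], ["patient_id", "date", "drug_name", "atc_code"]
    )
    prescriptions = [
        Prescription(
            r.patient_id,
            _parse_date(r.date, table="medication", row=i, column="date"),
            r.drug_name,
            r.atc_code,
        )
        for i, r in enumerate(mdf.itertuples(index=False), start=1)
    ]

    return Cohort(
        patients=patients,
        billing=billing,
        encounters=encounters,
        conditions=conditions,
        prescriptions=prescriptions,
        reference_date=reference_date,
    ).validate()


def _iso(d: Optional[datetime.date]) -> str:
    return d.isoformat() if d is not None else ""


def write_cohort(cohort: Cohort, directory: Path | str) -> dict[str, Path]:
    """Write the five cohort tables to ``directory``; returns the paths.

    ``load_cohort(write_cohort(c))`` reproduces ``c`` field for field.
    """
    cohort.validate()
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    frames = {
        "patients": pd.DataFrame(
            [(p.patient_id, _iso(p.birth_date), p.sex) for p in cohort.patients],
            columns=["patient_id", "birth_date", "sex"],
        ),
        "billing": pd.DataFrame(
            [(b.patient_id, _iso(b.date), b.diagnosis_code) for b in cohort.billing],
            columns=["patient_id", "date", "diagnosis_code"],
        ),
        "encounters": pd.DataFrame(
            [
                (e.patient_id, _iso(e.date), e.diagnosis_code, e.diagnosis_text)
                for e in cohort.encounters
            ],
            columns=["patient_id", "date", "diagnosis_code", "diagnosis_text"],
        ),
        "conditions": pd.DataFrame(
            [
                (c.patient_id, _iso(c.date_onset), c.condition_code, c.condition_text)
                for c in cohort.conditions
            ],
            columns=["patient_id", "date_onset", "condition_code", "condition_text"],
        ),
        "prescriptions": pd.DataFrame(
            [
                (rx.patient_id, _iso(rx.date), rx.drug_name, rx.atc_code)
                for rx in cohort.prescriptions
            ],
            columns=["patient_id", "date", "drug_name", "atc_code"],
        ),
    }
    paths: dict[str, Path] = {}
    for key, name in TABLE_FILES.items():
        path = base / name
        frames[key].to_csv(path, index=False, lineterminator="\n")
        paths[key] = path
    return paths


def load_labels(path: Path | str, column: str = "gold_case") -> dict[str, bool]:
    """Read a two-column ``patient_id,<column>`` label table (values 1/0)."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    for col in ("patient_id", column):
        if col not in df.columns:
            raise CohortError(f"{Path(path).name}: missing column {col!r}")
    labels: dict[str, bool] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        value = getattr(rec, column).strip()
        if value not in {"0", "1"}:
            raise CohortError(f"{Path(path).name} row {i}: label must be 0 or 1, got {value!r}")
        if rec.patient_id in labels:
            raise CohortError(f"{Path(path).name} row {i}: duplicate patient_id {rec.patient_id!r}")
        labels[rec.patient_id] = value == "1"
    return labels


def write_labels(
    labels: Mapping[str, bool], path: Path | str, column: str = "gold_case"
) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(pid, int(v)) for pid, v in labels.items()], columns=["patient_id", column]
    ).to_csv(path, index=False, lineterminator="\n")
    return path
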