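"""Synthetic CPCSSN-like cohort generator with known gold labels.

Emulates the record phenomenology the case definition has to cope with:
ICD-9 493 billing and encounter codes, free-text diagnosis labels in
assorted capitalisations ("asthma", "Asthmatic bronchitis", ...),
uncertainty notations that must be excluded ("asthma query", "?asthma",
"asthma?"), concurrent "acute bronchitis" labels, ATC-coded reliever and
controller prescriptions (occasionally name-only rows), and sparse
"suspected" records from very young children.  Documentation
probabilities are configurable; none are claims about real CPCSSN data.

When ``target_sensitivity``/``target_specificity`` are set, gold-positive
patients are generated fully documented (guaranteed to classify as
cases) with probability equal to the target sensitivity and
sub-threshold otherwise, and symmetrically for gold-negatives — so the
classifier's expected operating point equals the targets and recovery
can be tested against a known truth.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .emr import (
    DEFAULT_REFERENCE_DATE,
    BillingEntry,
    Cohort,
    EncounterDiagnosis,
    HealthCondition,
    Patient,
    Prescription,
    age_in_years,
    write_cohort,
    write_labels,
)

#: Drug names for the qualifying ATC codes, for realistic prescription rows.
ATC_NAMES: dict[str, str] = {
    "R03BA01": "Beclomethasone",
    "R03BA02": "Budesonide",
    "R03BA05": "Fluticasone propionate",
    "R03BA06": "Triamcinolone",
    "R03BA07": "Mometasone",
    "R03BA08": "Ciclesonide",
    "R03AK06": "Salmeterol and fluticasone",
    "R03AK07": "Formoterol and budesonide",
    "R03AK08": "Formoterol and beclometasone",
    "R03AK09": "Formoterol and mometasone",
    "R03AC02": "Salbutamol",
    "R03AC03": "Terbutaline",
    "R03AC04": "Fenoterol",
    "R03AC12": "Salmeterol",
    "R03AC13": "Formoterol",
    "R03AC18": "Indacaterol",
    "R03DC01": "Zafirlukast",
    "R03DC03": "Montelukast",
    "H02AB02": "Dexamethasone",
    "H02AB06": "Prednisolone",
    "H02AB07": "Prednisone",
    "R03BB01": "Ipratropium bromide",
}

RELIEVER_CODES = ("R03AC02", "R03AC03")
CONTROLLER_CODES = tuple(c for c in ATC_NAMES if c not in RELIEVER_CODES)

#: Qualifying free-text variants (capitalisation/punctuation exercised).
ASTHMA_TEXTS = (
    "asthma",
    "Asthma",
    "ASTHMA",
    "asthma, mild",
    "Asthmatic bronchitis",
    "asthma exacerbation",
    "(asthma)",
)

#: Uncertainty notations that the exclusion globs must reject.
EXCLUSION_TEXTS = (
    "asthma query",
    "query asthma",
    "?asthma",
    "asthma?",
    "Asthma - query",
    "query: asthma",
)

#: Plausible non-asthma respiratory labels for controls.
DISTRACTOR_TEXTS = (
    "acute bronchitis",
    "Acute bronchitis",
    "bronchiolitis",
    "URTI",
    "croup",
    "gastroesophageal reflux",
)


class CriterionProfile(BaseModel):
    """Per-criterion documentation probabilities for one gold stratum."""

    p_billing_code: float = 0.0
    p_encounter_code: float = 0.0
    p_encounter_text: float = 0.0
    p_condition: float = 0.0
    #: Distribution over the number of qualifying prescription rows.
    rx_count_dist: dict[int, float] = Field(default_factory=lambda: {0: 1.0})
    p_exclusion_text: float = 0.0
    p_distractor_text: float = 0.0

    @field_validator(
        "p_billing_code",
        "p_encounter_code",
        "p_encounter_text",
        "p_condition",
        "p_exclusion_text",
        "p_distractor_text",
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {v}")
        return v

    @field_validator("rx_count_dist")
    @classmethod
    def _dist(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("rx_count_dist must be non-empty")
        if any(k < 0 for k in v) or any(p < 0 for p in v.values()):
            raise ValueError("rx_count_dist keys and masses must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("rx_count_dist must sum to 1")
        return dict(sorted(v.items()))


def default_case_profile() -> CriterionProfile:
    """Documentation of children the reviewers would call asthmatic:
    mostly labelled and mostly on two or more qualifying prescriptions."""
    return CriterionProfile(
        p_billing_code=0.55,
        p_encounter_code=0.30,
        p_encounter_text=0.80,
        p_condition=0.45,
        rx_count_dist={0: 0.04, 1: 0.12, 2: 0.40, 3: 0.28, 4: 0.16},
        p_exclusion_text=0.05,
        p_distractor_text=0.20,
    )


def default_control_profile() -> CriterionProfile:
    """Documentation of non-asthmatic children: mostly empty records with
    occasional uncertainty notes, respiratory distractor labels and a
    small single-reliever tail (transient viral wheeze)."""
    return CriterionProfile(
        p_billing_code=0.008,
        p_encounter_code=0.004,
        p_encounter_text=0.010,
        p_condition=0.004,
        rx_count_dist={0: 0.90, 1: 0.085, 2: 0.015},
        p_exclusion_text=0.08,
        p_distractor_text=0.15,
    )


class CalibrationError(ValueError):
    """The requested operating point cannot be generated from the profiles."""


class CohortConfig(BaseModel):
    """Generative parameters for a synthetic labelled cohort."""

    n_patients: int = 1000
    prevalence: float = 0.143
    age_low: int = 1
    age_high: int = 17
    seed: int = 0
    case_profile: CriterionProfile = Field(default_factory=default_case_profile)
    control_profile: CriterionProfile = Field(default_factory=default_control_profile)
    #: Fraction of gold-positives generated as sparse "suspected" records
    #: (very young patients with too little documentation to classify).
    suspected_fraction: float = 0.06
    target_sensitivity: Optional[float] = None
    target_specificity: Optional[float] = None
    reference_date: datetime.date = DEFAULT_REFERENCE_DATE

    @field_validator("n_patients")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_patients must be >= 0")
        return v

    @field_validator("prevalence", "suspected_fraction")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"proportion out of [0, 1]: {v}")
        return v

    @field_validator("target_sensitivity", "target_specificity")
    @classmethod
    def _target(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 < v <= 1.0:
            raise ValueError(f"target must be in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _ages(self) -> "CohortConfig":
        if self.age_low > self.age_high:
            raise ValueError("age_low must not exceed age_high")
        if self.age_low < 0:
            raise ValueError("age_low must be >= 0")
        return self


@dataclass
class LabelledCohort:
    """A synthetic cohort with its generating truth."""

    cohort: Cohort
    gold: dict[str, bool]
    suspected: dict[str, bool]
    config: CohortConfig

    def write(self, directory: Path | str) -> dict[str, Path]:
        """Write the five tables, gold.csv and a provenance file."""
        base = Path(directory)
        paths = write_cohort(self.cohort, base)
        paths["gold"] = write_labels(self.gold, base / "gold.csv")
        prov = base / "provenance.json"
        prov.write_text(
            json.dumps(
                {
                    "generator": "asthmafinder.simulate",
                    "config": json.loads(self.config.model_dump_json()),
                },
                indent=2,
            )
            + "\n"
        )
        paths["provenance"] = prov
        return paths


def calibrate_profiles(
    target_sensitivity: float,
    target_specificity: float,
    base_config: Optional[CohortConfig] = None,
) -> CohortConfig:
    """Return a config whose generative mixture gives the classifier an
    expected per-patient operating point equal to the targets.

    Gold-positives are fully documented (guaranteed cases) with
    probability ``target_sensitivity``; gold-negatives are generated with
    case-like documentation with probability ``1 - target_specificity``.
    Requires the case prescription-count distribution to have support at
    two or more prescriptions.
    """
    base = base_config or CohortConfig()
    config = base.model_copy(
        update={
            "target_sensitivity": target_sensitivity,
            "target_specificity": target_specificity,
        }
    )
    if not any(k >= 2 for k in config.case_profile.rx_count_dist):
        raise CalibrationError(
            "case_profile.rx_count_dist has no mass at >= 2 prescriptions; "
            "fully documented cases cannot be generated"
        )
    return config


# ---------------------------------------------------------------------------
# Generation


def _sample_date(
    rng: np.random.Generator, birth: datetime.date, reference: datetime.date
) -> datetime.date:
    span = (reference - birth).days
    back = int(rng.integers(0, min(span, 1095) + 1))
    return reference - datetime.timedelta(days=back)


def _sample_rx_count(rng: np.random.Generator, dist: dict[int, float]) -> int:
    counts = list(dist.keys())
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(counts, p=probs))


def _conditional_rx_count(
    rng: np.random.Generator, dist: dict[int, float], minimum: int
) -> int:
    support = {k: p for k, p in dist.items() if k >= minimum and p > 0}
    if not support:
        raise CalibrationError(
            f"rx_count_dist has no mass at >= {minimum} prescriptions"
        )
    return _sample_rx_count(rng, support)


class _PatientBuilder:
    """Accumulates one patient's rows from a single random stream."""

    def __init__(
        self, rng: np.random.Generator, pid: str, birth: datetime.date, ref: datetime.date
    ):
        self.rng = rng
        self.pid = pid
        self.birth = birth
        self.ref = ref
        self.billing: list[BillingEntry] = []
        self.encounters: list[EncounterDiagnosis] = []
        self.conditions: list[HealthCondition] = []
        self.prescriptions: list[Prescription] = []

    def _date(self) -> datetime.date:
        return _sample_date(self.rng, self.birth, self.ref)

    def add_billing_code(self, code: str = "493") -> None:
        # real extracts carry sub-codes too
        variant = self.rng.choice([code, f"{code}.0", f"{code}.90"])
        self.billing.append(BillingEntry(self.pid, self._date(), str(variant)))

    def add_encounter_code(self, code: str = "493") -> None:
        self.encounters.append(
            EncounterDiagnosis(self.pid, self._date(), diagnosis_code=str(code))
        )

    def add_encounter_text(self, text: str) -> None:
        self.encounters.append(
            EncounterDiagnosis(self.pid, self._date(), diagnosis_text=text)
        )

    def add_condition_text(self, text: str) -> None:
        self.conditions.append(
            HealthCondition(self.pid, self._date(), condition_text=text)
        )

    def add_prescription(self, prefer_reliever: bool) -> None:
        if prefer_reliever:
            code = str(self.rng.choice(RELIEVER_CODES))
        else:
            pool = RELIEVER_CODES + CONTROLLER_CODES
            code = str(self.rng.choice(pool))
        name = ATC_NAMES[code]
        # ~10% of rows arrive without an ATC code: name-fallback territory
        if self.rng.random() < 0.10:
            self.prescriptions.append(
                Prescription(self.pid, self._date(), drug_name=f"{name} inhaler", atc_code="")
            )
        else:
            self.prescriptions.append(
                Prescription(self.pid, self._date(), drug_name=name, atc_code=code)
            )

    def add_profile_draw(self, profile: CriterionProfile, *, suppress_criteria: bool = False,
                         max_rx: Optional[int] = None, force_min_rx: Optional[int] = None) -> None:
        rng = self.rng
        if not suppress_criteria:
            if rng.random() < profile.p_billing_code:
                self.add_billing_code()
            if rng.random() < profile.p_encounter_code:
                self.add_encounter_code()
            if rng.random() < profile.p_encounter_text:
                self.add_encounter_text(str(rng.choice(ASTHMA_TEXTS)))
            if rng.random() < profile.p_condition:
                self.add_condition_text(str(rng.choice(ASTHMA_TEXTS)))
        if rng.random() < profile.p_exclusion_text:
            self.add_encounter_text(str(rng.choice(EXCLUSION_TEXTS)))
        if rng.random() < profile.p_distractor_text:
            self.add_encounter_text(str(rng.choice(DISTRACTOR_TEXTS)))
        if force_min_rx is not None:
            n_rx = _conditional_rx_count(rng, profile.rx_count_dist, force_min_rx)
        else:
            n_rx = _sample_rx_count(rng, profile.rx_count_dist)
        if max_rx is not None:
            n_rx = min(n_rx, max_rx)
        for i in range(n_rx):
            self.add_prescription(prefer_reliever=(i == 0))


def generate(config: CohortConfig) -> LabelledCohort:
    """Draw a labelled cohort from a single seeded random stream.

    Deterministic given the config (same config + seed ⇒ byte-identical
    written tables); patient order is generation order.
    """
    # Pydantic has validated the config; fail fast on calibration issues
    # before any sampling.
    if config.target_sensitivity is not None or config.target_specificity is not None:
        if not any(
            k >= 2 and p > 0 for k, p in config.case_profile.rx_count_dist.items()
        ):
            raise CalibrationError(
                "calibrated generation needs case rx_count_dist mass at >= 2"
            )

    rng = np.random.default_rng(config.seed)
    ref = config.reference_date
    patients: list[Patient] = []
    billing: list[BillingEntry] = []
    encounters: list[EncounterDiagnosis] = []
    conditions: list[HealthCondition] = []
    prescriptions: list[Prescription] = []
    gold: dict[str, bool] = {}
    suspected: dict[str, bool] = {}

    calibrated = (
        config.target_sensitivity is not None
        and config.target_specificity is not None
    )
    width = max(5, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        is_gold = bool(rng.random() < config.prevalence)
        is_suspected = False

        # Decide the documentation branch first; "sparse" records belong
        # to very young children, so the branch can constrain the age.
        if calibrated:
            if is_gold:
                if rng.random() < config.target_sensitivity:
                    branch = "case_full"
                elif rng.random() < 0.3:
                    branch = "sparse"  # suspected records count as misses
                    is_suspected = True
                else:
                    branch = "case_sub"
            else:
                if rng.random() < 1.0 - config.target_specificity:
                    branch = "case_full"
                else:
                    branch = "control_safe"
        else:
            if is_gold and rng.random() < config.suspected_fraction:
                branch = "sparse"
                is_suspected = True
            elif is_gold:
                branch = "case_free"
            else:
                branch = "control_free"

        age = int(rng.integers(config.age_low, config.age_high + 1))
        if branch == "sparse" and config.age_low <= 2:
            age = int(rng.integers(max(config.age_low, 1), min(2, config.age_high) + 1))

        # birth date back-computed so completed age at ref equals `age`
        anniversary = ref - datetime.timedelta(days=round(age * 365.2425))
        offset = int(rng.integers(0, 364))
        birth = anniversary - datetime.timedelta(days=offset)
        # guard against drift across leap years
        while age_in_years(birth, ref) > age:
            birth += datetime.timedelta(days=1)
        while age_in_years(birth, ref) < age:
            birth -= datetime.timedelta(days=1)

        sex = "M" if rng.random() < 0.5 else "F"
        patients.append(Patient(pid, birth, sex))
        gold[pid] = is_gold
        builder = _PatientBuilder(rng, pid, birth, ref)

        if branch == "sparse":
            # one ambiguous row: an uncertainty note or a lone reliever
            if rng.random() < 0.5:
                builder.add_encounter_text(str(rng.choice(EXCLUSION_TEXTS)))
            else:
                builder.add_prescription(prefer_reliever=True)
        elif branch == "case_full":
            # fully documented: guaranteed >= 2 qualifying scripts
            builder.add_profile_draw(config.case_profile, force_min_rx=2)
        elif branch == "case_sub":
            # a label without enough prescriptions: never classifies
            if rng.random() < 0.6:
                builder.add_encounter_text(str(rng.choice(ASTHMA_TEXTS)))
            elif rng.random() < 0.5:
                builder.add_billing_code()
            else:
                builder.add_prescription(prefer_reliever=True)
        elif branch == "control_safe":
            # guaranteed non-case: no qualifying criteria, <= 1 script
            builder.add_profile_draw(
                config.control_profile, suppress_criteria=True, max_rx=1
            )
        else:
            profile = config.case_profile if is_gold else config.control_profile
            builder.add_profile_draw(profile)

        suspected[pid] = is_suspected
        billing.extend(builder.billing)
        encounters.extend(builder.encounters)
        conditions.extend(builder.conditions)
        prescriptions.extend(builder.prescriptions)

    cohort = Cohort(
        patients=patients,
        billing=billing,
        encounters=encounters,
        conditions=conditions,
        prescriptions=prescriptions,
        reference_date=ref,
    ).validate()
    return LabelledCohort(cohort=cohort, gold=gold, suspected=suspected, config=config)
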