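"""Operational case definition for pediatric asthma.

The rule combines four EMR criterion categories — billing diagnoses,
encounter diagnoses, health-condition (problem-list) entries and
prescribed medications — over a patient's whole record:

* ICD-9 rubric 493 and its derivatives (493.0, 493.90, ...) in any of
  the three diagnosis categories;
* any free-text token starting with ``asth`` in encounter or condition
  text, except uncertainty notations ("asthma query", "?asthma", ...)
  matched by whole-field glob exclusion patterns;
* prescriptions for asthma medications identified by 22 ATC codes
  (relievers, inhaled and oral corticosteroids, combination inhalers and
  leukotriene receptor antagonists) or, when the ATC code is missing, by
  drug-name substring.

A patient aged 1-17 years (inclusive, completed years at the reference
date) is a case when they have at least two qualifying prescriptions, or
one qualifying prescription together with at least one qualifying
diagnosis criterion.  Diagnosis labels alone, with no prescription, do
not make a case under the default rule.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .emr import (
    ATC_SHAPE,
    Cohort,
    Patient,
    Prescription,
    age_in_years,
)

#: ATC codes of the qualifying asthma medications (relievers, inhaled and
#: systemic corticosteroids, combination inhalers, leukotriene receptor
#: antagonists, ipratropium).
DEFAULT_ATC_CODES: frozenset[str] = frozenset(
    {
        "R03BA01",  # beclomethasone
        "R03BA02",  # budesonide
        "R03BA05",  # fluticasone
        "R03BA06",  # triamcinolone
        "R03BA07",  # mometasone
        "R03BA08",  # ciclesonide
        "R03AK06",  # salmeterol and fluticasone
        "R03AK07",  # formoterol and budesonide
        "R03AK08",  # formoterol and beclometasone
        "R03AK09",  # formoterol and mometasone
        "R03AC02",  # salbutamol
        "R03AC03",  # terbutaline
        "R03AC04",  # fenoterol
        "R03AC12",  # salmeterol
        "R03AC13",  # formoterol
        "R03AC18",  # indacaterol
        "R03DC01",  # zafirlukast
        "R03DC03",  # montelukast
        "H02AB02",  # dexamethasone
        "H02AB06",  # prednisolone
        "H02AB07",  # prednisone
        "R03BB01",  # ipratropium bromide
    }
)

#: Lower-cased drug-name fragments used when a prescription row carries no
#: ATC code.  Both "beclomethasone" and "beclometasone" spellings occur.
DEFAULT_DRUG_NAMES: frozenset[str] = frozenset(
    {
        "beclomethasone",
        "beclometasone",
        "budesonide",
        "fluticasone",
        "triamcinolone",
        "mometasone",
        "ciclesonide",
        "salmeterol",
        "formoterol",
        "salbutamol",
        "terbutaline",
        "fenoterol",
        "indacaterol",
        "zafirlukast",
        "montelukast",
        "dexamethasone",
        "prednisolone",
        "prednisone",
        "ipratropium",
    }
)

DEFAULT_EXCLUDE_PATTERNS = (
    "*asthma*query*",
    "*query*asthma*",
    "*asthma*?*",
    "*?*asthma*",
)


class CaseDefinitionConfig(BaseModel):
    """Tunable parameters of the case definition.

    The defaults implement the operational definition verbatim; the
    switches (`prescription_counting`, `allow_diagnosis_only`) exist for
    sensitivity analyses and are off by default.
    """

    icd9_prefix: str = "493"
    text_include_patterns: list[str] = Field(default_factory=lambda: ["asth*"])
    text_exclude_patterns: list[str] = Field(
        default_factory=lambda: list(DEFAULT_EXCLUDE_PATTERNS)
    )
    atc_codes: set[str] = Field(default_factory=lambda: set(DEFAULT_ATC_CODES))
    drug_names: set[str] = Field(default_factory=lambda: set(DEFAULT_DRUG_NAMES))
    age_min: int = 1
    age_max: int = 17
    min_prescriptions_alone: int = 2
    min_prescriptions_with_other_criterion: int = 1
    #: "rows" counts prescription rows; "distinct_drug"/"distinct_date"
    #: count unique drugs or unique fill dates instead.
    prescription_counting: Literal["rows", "distinct_drug", "distinct_date"] = "rows"
    #: When true, qualifying diagnosis criteria alone (zero prescriptions)
    #: also make a case — an exploratory arm, not the default rule.
    allow_diagnosis_only: bool = False

    @field_validator("atc_codes")
    @classmethod
    def _atc_shape(cls, v: set[str]) -> set[str]:
        v = {code.strip().upper() for code in v}
        bad = [code for code in v if not ATC_SHAPE.match(code)]
        if bad:
            raise ValueError(f"malformed ATC code(s): {sorted(bad)}")
        return v

    @field_validator("drug_names")
    @classmethod
    def _lower_names(cls, v: set[str]) -> set[str]:
        return {name.strip().lower() for name in v if name.strip()}

    @model_validator(mode="after")
    def _check_bounds(self) -> "CaseDefinitionConfig":
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if not (
            self.min_prescriptions_alone
            > self.min_prescriptions_with_other_criterion
            >= 1
        ):
            raise ValueError(
                "require min_prescriptions_alone > "
                "min_prescriptions_with_other_criterion >= 1"
            )
        return self


@dataclass(frozen=True)
class CriteriaProfile:
    """Per-patient evaluation of the criterion categories plus eligibility."""

    patient_id: str
    eligible_age: bool
    age_years: Optional[int]
    billing_hit: bool
    encounter_hit: bool
    condition_hit: bool
    n_qualifying_prescriptions: int
    is_case: bool

    @property
    def any_diagnosis_hit(self) -> bool:
        return self.billing_hit or self.encounter_hit or self.condition_hit


# ---------------------------------------------------------------------------
# Matching primitives

_ICD9_TAG = re.compile(r"^\s*ICD-?9\s*:\s*", re.IGNORECASE)
_WS = re.compile(r"\s+")


def _normalize_text(text: str) -> str:
    return _WS.sub(" ", text).strip().lower()


def match_icd9_asthma(code: str, prefix: str = "493") -> bool:
    """True when the code, after trimming and dropping a leading
    ``ICD-9:`` style tag, begins with ``prefix`` — so 493, 493.0 and
    493.90 all match the asthma rubric."""
    cleaned = _ICD9_TAG.sub("", code).strip()
    return bool(cleaned) and cleaned.startswith(prefix)


def match_include_text(text: str, patterns: Iterable[str] = ("asth*",)) -> bool:
    """Token-initial prefix match, case-insensitive.

    A pattern ``asth*`` matches any whitespace-delimited token beginning
    with ``asth``; punctuation hugging a token ("(asthma)") is ignored
    when locating the token start.
    """
    normalized = _normalize_text(text)
    if not normalized:
        return False
    tokens = re.findall(r"[^\W_]+", normalized, flags=re.UNICODE)
    prefixes = [p.lower().rstrip("*") for p in patterns]
    return any(tok.startswith(pref) for tok in tokens for pref in prefixes if pref)


def glob_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile an exclusion glob where ``*`` matches any (possibly empty)
    sequence and ``?`` is the literal question mark, anchored to the
    whole field."""
    parts = [".*" if ch == "*" else re.escape(ch) for ch in pattern.lower()]
    return re.compile("".join(parts), re.DOTALL)


def match_exclude_text(
    text: str, patterns: Iterable[str] = DEFAULT_EXCLUDE_PATTERNS
) -> bool:
    """True when any exclusion glob matches the whole normalized field.

    The patterns target uncertainty notations ("asthma query", "asthma?",
    "?asthma"), so ``?`` is a literal character, never a wildcard.
    """
    normalized = _normalize_text(text)
    if not normalized:
        return False
    return any(glob_to_regex(p).fullmatch(normalized) for p in patterns)


def qualifying_text(
    text: str, config: Optional[CaseDefinitionConfig] = None
) -> bool:
    """Included text that is not excluded: mentions asthma without an
    uncertainty qualifier."""
    config = config or CaseDefinitionConfig()
    return match_include_text(text, config.text_include_patterns) and not (
        match_exclude_text(text, config.text_exclude_patterns)
    )


def is_asthma_medication(
    rx: Prescription, config: Optional[CaseDefinitionConfig] = None
) -> bool:
    """A prescription qualifies by ATC code; rows without an ATC code fall
    back to a drug-name substring match."""
    config = config or CaseDefinitionConfig()
    code = rx.atc_code.strip().upper()
    if code:
        return code in config.atc_codes
    name = rx.drug_name.strip().lower()
    return bool(name) and any(frag in name for frag in config.drug_names)


# ---------------------------------------------------------------------------
# Classification


def classify(profile: CriteriaProfile, config: Optional[CaseDefinitionConfig] = None) -> bool:
    """Apply the combination rule to an evaluated profile.

    Case ⇔ eligible age AND (≥2 qualifying prescriptions, or ≥1
    qualifying prescription together with a billing, encounter or
    condition hit).  With ``allow_diagnosis_only`` a diagnosis hit alone
    also suffices.
    """
    config = config or CaseDefinitionConfig()
    if not profile.eligible_age:
        return False
    n = profile.n_qualifying_prescriptions
    if n >= config.min_prescriptions_alone:
        return True
    if n >= config.min_prescriptions_with_other_criterion and profile.any_diagnosis_hit:
        return True
    if config.allow_diagnosis_only and profile.any_diagnosis_hit:
        return True
    return False


def evaluate_criteria(
    patient: Patient,
    *,
    billing: Iterable = (),
    encounters: Iterable = (),
    conditions: Iterable = (),
    prescriptions: Iterable[Prescription] = (),
    config: Optional[CaseDefinitionConfig] = None,
    reference_date=None,
) -> CriteriaProfile:
    """Evaluate all criterion categories for one patient.

    Exclusion patterns are local to each text field: an "asthma query"
    encounter never cancels a qualifying hit on another row.  Billing is
    code-only.  A missing birth date makes the patient ineligible.
    """
    from .emr import DEFAULT_REFERENCE_DATE

    config = config or CaseDefinitionConfig()
    reference_date = reference_date or DEFAULT_REFERENCE_DATE

    if patient.birth_date is None:
        age: Optional[int] = None
        eligible = False
    else:
        age = age_in_years(patient.birth_date, reference_date)
        eligible = config.age_min <= age <= config.age_max

    billing_hit = any(
        match_icd9_asthma(b.diagnosis_code, config.icd9_prefix) for b in billing
    )
    encounter_hit = any(
        match_icd9_asthma(e.diagnosis_code, config.icd9_prefix)
        or qualifying_text(e.diagnosis_text, config)
        for e in encounters
    )
    condition_hit = any(
        match_icd9_asthma(c.condition_code, config.icd9_prefix)
        or qualifying_text(c.condition_text, config)
        for c in conditions
    )

    qualifying = [rx for rx in prescriptions if is_asthma_medication(rx, config)]
    if config.prescription_counting == "rows":
        n_rx = len(qualifying)
    elif config.prescription_counting == "distinct_drug":
        n_rx = len(
            {
                (rx.atc_code.strip().upper() or rx.drug_name.strip().lower())
                for rx in qualifying
            }
        )
    else:  # distinct_date
        n_rx = len({rx.date for rx in qualifying})

    profile = CriteriaProfile(
        patient_id=patient.patient_id,
        eligible_age=eligible,
        age_years=age,
        billing_hit=billing_hit,
        encounter_hit=encounter_hit,
        condition_hit=condition_hit,
        n_qualifying_prescriptions=n_rx,
        is_case=False,
    )
    return dataclasses.replace(profile, is_case=classify(profile, config))


def classify_cohort(
    cohort: Cohort, config: Optional[CaseDefinitionConfig] = None
) -> pd.DataFrame:
    """Classify every patient in a cohort.

    Returns one row per patient: ``patient_id, is_case, age_years,
    billing_hit, encounter_hit, condition_hit, n_prescriptions``;
    deterministic given cohort and configuration.
    """
    config = config or CaseDefinitionConfig()
    by_pid: dict[str, dict[str, list]] = {
        p.patient_id: {"b": [], "e": [], "c": [], "rx": []} for p in cohort.patients
    }
    for b in cohort.billing:
        by_pid[b.patient_id]["b"].append(b)
    for e in cohort.encounters:
        by_pid[e.patient_id]["e"].append(e)
    for c in cohort.conditions:
        by_pid[c.patient_id]["c"].append(c)
    for rx in cohort.prescriptions:
        by_pid[rx.patient_id]["rx"].append(rx)

    records = []
    for patient in cohort.patients:
        rows = by_pid[patient.patient_id]
        prof = evaluate_criteria(
            patient,
            billing=rows["b"],
            encounters=rows["e"],
            conditions=rows["c"],
            prescriptions=rows["rx"],
            config=config,
            reference_date=cohort.reference_date,
        )
        records.append(
            {
                "patient_id": prof.patient_id,
                "is_case": prof.is_case,
                "age_years": prof.age_years if prof.age_years is not None else pd.NA,
                "billing_hit": prof.billing_hit,
                "encounter_hit": prof.encounter_hit,
                "condition_hit": prof.condition_hit,
                "n_prescriptions": prof.n_qualifying_prescriptions,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "patient_id",
            "is_case",
            "age_years",
            "billing_hit",
            "encounter_hit",
            "condition_hit",
            "n_prescriptions",
        ],
    )
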