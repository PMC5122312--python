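"""Diagnostic-accuracy and inter-rater statistics.

Given per-patient algorithm labels and gold-standard chart-review labels,
this module builds 2×2 confusion matrices, computes sensitivity,
specificity, PPV and NPV with binomial confidence intervals
(Clopper–Pearson exact by default, Wilson score optionally), Cohen's
kappa and percent agreement for two raters, and assembles the
age-stratified validation report (default bands 1–17, 3–17 and 6–17
years, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .emr import Cohort, age_in_years

DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = ((1, 17), (3, 17), (6, 17))

CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


class LabelMismatchError(ValueError):
    """Algorithm and gold label tables cover different patients."""


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its two-sided confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(100 * self.point, decimals),
            round_half_up(100 * self.ci_low, decimals),
            round_half_up(100 * self.ci_high, decimals),
        )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, as printed validation tables do
    (87.45 → 87.5), rather than banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def binomial_ci(
    successes: int,
    n: int,
    method: str = "clopper-pearson",
    level: float = 0.95,
) -> tuple[float, float]:
    """Two-sided binomial interval for ``successes`` out of ``n``.

    ``clopper-pearson`` is the exact beta-quantile interval with the
    conventional boundary values (low = 0 at 0 successes, high = 1 at n);
    ``wilson`` is the score interval.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {sorted(CI_METHODS)}")
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"need 0 <= successes <= n with n >= 1, got {successes}/{n}")
    low, high = proportion_confint(successes, n, alpha=1 - level, method=CI_METHODS[method])
    return float(low), float(high)


def _proportion_metric(
    numerator: int,
    denominator: int,
    name: str,
    method: str,
    level: float,
) -> MetricEstimate:
    if denominator == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    low, high = binomial_ci(numerator, denominator, method=method, level=level)
    return MetricEstimate(numerator / denominator, low, high, level, method)


def sensitivity(
    cm: ConfusionMatrix, method: str = "clopper-pearson", level: float = 0.95
) -> MetricEstimate:
    """TP / (TP + FN): the fraction of gold cases the algorithm finds."""
    return _proportion_metric(cm.tp, cm.tp + cm.fn, "sensitivity", method, level)


def specificity(
    cm: ConfusionMatrix, method: str = "clopper-pearson", level: float = 0.95
) -> MetricEstimate:
    """TN / (TN + FP): the fraction of gold non-cases correctly cleared."""
    return _proportion_metric(cm.tn, cm.tn + cm.fp, "specificity", method, level)


def ppv(
    cm: ConfusionMatrix, method: str = "clopper-pearson", level: float = 0.95
) -> MetricEstimate:
    """TP / (TP + FP): probability a flagged patient is a true case."""
    return _proportion_metric(cm.tp, cm.tp + cm.fp, "ppv", method, level)


def npv(
    cm: ConfusionMatrix, method: str = "clopper-pearson", level: float = 0.95
) -> MetricEstimate:
    """TN / (TN + FN): probability an unflagged patient is a true non-case."""
    return _proportion_metric(cm.tn, cm.tn + cm.fn, "npv", method, level)


METRIC_FUNCS = {
    "sensitivity": sensitivity,
    "specificity": specificity,
    "ppv": ppv,
    "npv": npv,
}


def _check_same_patients(a: Mapping[str, bool], b: Mapping[str, bool]) -> None:
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise LabelMismatchError(
            "label tables cover different patients; "
            f"examples only in first: {only_a}, only in second: {only_b}"
        )


def build_confusion(
    algorithm_labels: Mapping[str, bool], gold_labels: Mapping[str, bool]
) -> ConfusionMatrix:
    """Cross-tabulate algorithm verdicts against gold-standard labels."""
    _check_same_patients(algorithm_labels, gold_labels)
    tp = fp = tn = fn = 0
    for pid, alg in algorithm_labels.items():
        gold = gold_labels[pid]
        if alg and gold:
            tp += 1
        elif alg and not gold:
            fp += 1
        elif not alg and gold:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def percent_agreement(
    labels_a: Mapping[str, bool], labels_b: Mapping[str, bool]
) -> float:
    """Fraction of patients on which two raters give the same label."""
    _check_same_patients(labels_a, labels_b)
    if not labels_a:
        raise ValueError("cannot compute agreement on an empty label set")
    same = sum(labels_a[pid] == labels_b[pid] for pid in labels_a)
    return same / len(labels_a)


def cohen_kappa(labels_a: Mapping[str, bool], labels_b: Mapping[str, bool]) -> float:
    """Chance-corrected two-rater agreement, (p_o − p_e)/(1 − p_e).

    Expected agreement p_e is the product of the raters' marginal
    proportions summed over the two categories.  Perfect observed
    agreement returns 1 by convention, including the degenerate case
    where both raters use a single category.
    """
    _check_same_patients(labels_a, labels_b)
    n = len(labels_a)
    if n == 0:
        raise ValueError("cannot compute kappa on an empty label set")
    p_o = sum(labels_a[pid] == labels_b[pid] for pid in labels_a) / n
    if p_o == 1.0:
        return 1.0
    pa1 = sum(labels_a.values()) / n
    pb1 = sum(labels_b.values()) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# Stratified validation report


@dataclass(frozen=True)
class StratumResult:
    label: str
    age_band: tuple[int, int]
    n: int
    confusion: ConfusionMatrix
    metrics: dict[str, Optional[MetricEstimate]]


@dataclass
class ValidationReport:
    """Machine form of an age-stratified validation table."""

    strata: list[StratumResult] = field(default_factory=list)
    method: str = "clopper-pearson"
    level: float = 0.95

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            row: dict = {
                "age_band": s.label,
                "n": s.n,
                "tp": s.confusion.tp,
                "fp": s.confusion.fp,
                "tn": s.confusion.tn,
                "fn": s.confusion.fn,
            }
            for name in METRIC_FUNCS:
                est = s.metrics[name]
                if est is None:
                    row[name] = row[f"{name}_low"] = row[f"{name}_high"] = math.nan
                else:
                    pct, low, high = est.as_percent()
                    row[name], row[f"{name}_low"], row[f"{name}_high"] = pct, low, high
            rows.append(row)
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        """Aligned plain-text table with percentages to one decimal."""
        header = (
            f"{'Age range':<12}{'n':>6}{'TP':>6}{'FP':>6}{'TN':>6}{'FN':>6}  "
            f"{'Sensitivity':<22}{'Specificity':<22}{'PPV':<22}{'NPV':<22}"
        )
        lines = [header, "-" * len(header)]
        for s in self.strata:
            cells = [
                f"{s.label:<12}{s.n:>6}{s.confusion.tp:>6}{s.confusion.fp:>6}"
                f"{s.confusion.tn:>6}{s.confusion.fn:>6}  "
            ]
            for name in METRIC_FUNCS:
                est = s.metrics[name]
                if est is None:
                    cells.append(f"{'--':<22}")
                else:
                    pct, low, high = est.as_percent()
                    cells.append(f"{pct:.1f} ({low:.1f}-{high:.1f})".ljust(22))
            lines.append("".join(cells))
        return "\n".join(lines)


def report_from_ages(
    ages: Mapping[str, Optional[int]],
    algorithm_labels: Mapping[str, bool],
    gold_labels: Mapping[str, bool],
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    method: str = "clopper-pearson",
    level: float = 0.95,
) -> ValidationReport:
    """Stratified report when patient ages are already known.

    Each band is an inclusive integer range; patients with missing ages
    fall outside every band.  An empty stratum reports undefined metrics
    (``None``) rather than raising.
    """
    _check_same_patients(algorithm_labels, gold_labels)
    missing = set(algorithm_labels) - set(ages)
    if missing:
        raise LabelMismatchError(
            f"labels include patients without ages, e.g. {sorted(missing)[:5]}"
        )
    report = ValidationReport(method=method, level=level)
    for lo, hi in age_bands:
        pids = [
            pid
            for pid in algorithm_labels
            if ages[pid] is not None and lo <= ages[pid] <= hi
        ]
        cm = ConfusionMatrix(
            tp=sum(algorithm_labels[p] and gold_labels[p] for p in pids),
            fp=sum(algorithm_labels[p] and not gold_labels[p] for p in pids),
            tn=sum(not algorithm_labels[p] and not gold_labels[p] for p in pids),
            fn=sum(not algorithm_labels[p] and gold_labels[p] for p in pids),
        )
        metrics: dict[str, Optional[MetricEstimate]] = {}
        for name, func in METRIC_FUNCS.items():
            try:
                metrics[name] = func(cm, method=method, level=level)
            except UndefinedMetricError:
                metrics[name] = None
        report.strata.append(
            StratumResult(
                label=f"{lo}-{hi}", age_band=(lo, hi), n=cm.total, confusion=cm, metrics=metrics
            )
        )
    return report


def stratified_report(
    cohort: Cohort,
    algorithm_labels: Mapping[str, bool],
    gold_labels: Mapping[str, bool],
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    reference_date=None,
    method: str = "clopper-pearson",
    level: float = 0.95,
) -> ValidationReport:
    """Age-stratified validation of algorithm labels against gold labels.

    Ages are completed years at the cohort reference date.  Labels must
    cover exactly the cohort's patients.
    """
    reference_date = reference_date or cohort.reference_date
    ages = {
        p.patient_id: (
            age_in_years(p.birth_date, reference_date)
            if p.birth_date is not None
            else None
        )
        for p in cohort.patients
    }
    if set(algorithm_labels) != set(ages):
        raise LabelMismatchError("labels do not cover exactly the cohort's patients")
    return report_from_ages(
        ages, algorithm_labels, gold_labels, age_bands, method=method, level=level
    )
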