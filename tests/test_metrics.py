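import math
import random

import numpy as np
import pytest
from scipy.stats import beta

from asthmafinder.metrics import (
    ConfusionMatrix,
    LabelMismatchError,
    UndefinedMetricError,
    binomial_ci,
    build_confusion,
    cohen_kappa,
    npv,
    percent_agreement,
    ppv,
    report_from_ages,
    round_half_up,
    sensitivity,
    specificity,
    stratified_report,
)
from asthmafinder.simulate import CohortConfig, generate

# Published three-stratum validation table: (band, TP, FP, TN, FN) and the
# four point estimates in percent to one decimal.
VALIDATION_TABLE = [
    ("1-17", ConfusionMatrix(125, 12, 845, 18), (87.4, 98.6, 91.2, 97.9)),
    ("3-17", ConfusionMatrix(124, 11, 752, 17), (87.9, 98.6, 91.9, 97.8)),
    ("6-17", ConfusionMatrix(108, 11, 585, 16), (87.1, 98.2, 90.8, 97.3)),
]


def _labels_for(cm: ConfusionMatrix):
    algorithm, gold = {}, {}
    cells = (
        [(True, True)] * cm.tp
        + [(True, False)] * cm.fp
        + [(False, False)] * cm.tn
        + [(False, True)] * cm.fn
    )
    for i, (a, g) in enumerate(cells):
        algorithm[f"p{i}"] = a
        gold[f"p{i}"] = g
    return algorithm, gold


def test_confusion_built_from_labels_matches_cell_counts():
    cm = VALIDATION_TABLE[0][1]
    algorithm, gold = _labels_for(cm)
    assert build_confusion(algorithm, gold) == cm
    assert cm.total == 1000


def test_confusion_agrees_with_naive_counting_oracle():
    rng = random.Random(42)
    algorithm = {f"p{i}": rng.random() < 0.3 for i in range(500)}
    gold = {f"p{i}": rng.random() < 0.15 for i in range(500)}
    cm = build_confusion(algorithm, gold)
    tp = sum(1 for k in algorithm if algorithm[k] and gold[k])
    fp = sum(1 for k in algorithm if algorithm[k] and not gold[k])
    fn = sum(1 for k in algorithm if not algorithm[k] and gold[k])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, 500 - tp - fp - fn)


def test_mismatched_patient_sets_rejected_with_examples():
    with pytest.raises(LabelMismatchError, match="p1"):
        build_confusion({"p0": True, "p1": False}, {"p0": True, "p2": False})


@pytest.mark.parametrize("band, cm, expected", VALIDATION_TABLE)
def test_point_estimates_match_published_percentages(band, cm, expected):
    got = (
        round_half_up(100 * sensitivity(cm).point),
        round_half_up(100 * specificity(cm).point),
        round_half_up(100 * ppv(cm).point),
        round_half_up(100 * npv(cm).point),
    )
    assert got == expected


def test_perfect_classifier_has_unit_sensitivity_and_ppv():
    cm = ConfusionMatrix(tp=50, fp=0, tn=200, fn=0)
    assert sensitivity(cm).point == 1.0
    assert ppv(cm).point == 1.0


def test_zero_denominator_raises_named_error():
    cm = ConfusionMatrix(tp=0, fp=0, tn=10, fn=0)
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        sensitivity(cm)
    with pytest.raises(UndefinedMetricError, match="ppv"):
        ppv(cm)


def test_metric_points_are_exact_ratios():
    cm = ConfusionMatrix(125, 12, 845, 18)
    assert sensitivity(cm).point * (cm.tp + cm.fn) == pytest.approx(cm.tp, abs=1e-9)
    assert specificity(cm).point * (cm.tn + cm.fp) == pytest.approx(cm.tn, abs=1e-9)


class TestBinomialCI:
    def test_boundary_conventions(self):
        assert binomial_ci(0, 20)[0] == 0.0
        assert binomial_ci(20, 20)[1] == 1.0

    def test_clopper_pearson_equals_frozen_beta_quantile_oracle(self):
        # beta.ppf(0.025, 125, 19) and beta.ppf(0.975, 126, 18), computed
        # independently and frozen
        low, high = binomial_ci(125, 143, method="clopper-pearson")
        assert low == pytest.approx(0.8083761523168151, abs=1e-12)
        assert high == pytest.approx(0.9236630967638977, abs=1e-12)

    @pytest.mark.parametrize("k, n", [(3, 10), (50, 60), (0, 5), (7, 7)])
    def test_clopper_pearson_tracks_live_beta_quantiles(self, k, n):
        low, high = binomial_ci(k, n)
        exp_low = 0.0 if k == 0 else beta.ppf(0.025, k, n - k + 1)
        exp_high = 1.0 if k == n else beta.ppf(0.975, k + 1, n - k)
        assert low == pytest.approx(float(exp_low), abs=1e-12)
        assert high == pytest.approx(float(exp_high), abs=1e-12)

    @pytest.mark.parametrize("method", ["clopper-pearson", "wilson"])
    def test_interval_contains_point_and_narrows_with_n(self, method):
        prev_width = None
        for n in (20, 80, 320, 1280):
            k = round(0.7 * n)
            low, high = binomial_ci(k, n, method=method)
            assert low <= k / n <= high
            width = high - low
            if prev_width is not None:
                assert width < prev_width
            prev_width = width

    def test_invalid_level_and_method_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 10, level=1.5)
        with pytest.raises(ValueError):
            binomial_ci(1, 10, method="jeffreys-ish")


class TestAgreement:
    def test_identical_vectors_agree_fully(self):
        labels = {f"p{i}": i % 3 == 0 for i in range(100)}
        assert percent_agreement(labels, labels) == 1.0
        assert cohen_kappa(labels, dict(labels)) == 1.0

    def test_three_discordant_of_100_gives_97_percent(self):
        a = {f"p{i}": i < 50 for i in range(100)}
        b = dict(a)
        for pid in ("p0", "p1", "p2"):
            b[pid] = not b[pid]
        assert percent_agreement(a, b) == pytest.approx(0.97)

    def test_kappa_hand_worked_symmetric_table(self):
        # 2x2 rater table (40,10 / 10,40): p_o = 0.8, p_e = 0.5, kappa = 0.6
        a, b = {}, {}
        cells = (
            [(True, True)] * 40
            + [(True, False)] * 10
            + [(False, True)] * 10
            + [(False, False)] * 40
        )
        for i, (x, y) in enumerate(cells):
            a[f"p{i}"], b[f"p{i}"] = x, y
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_kappa_matches_sklearn_on_random_labels(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = random.Random(7)
        ids = [f"p{i}" for i in range(300)]
        a = {pid: rng.random() < 0.4 for pid in ids}
        b = {pid: rng.random() < 0.6 for pid in ids}
        expected = sklearn_metrics.cohen_kappa_score(
            [a[p] for p in ids], [b[p] for p in ids]
        )
        assert cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_kappa_near_zero_for_independent_raters(self):
        rng = np.random.default_rng(11)
        kappas = []
        for _ in range(40):
            a = {f"p{i}": bool(v) for i, v in enumerate(rng.random(400) < 0.5)}
            b = {f"p{i}": bool(v) for i, v in enumerate(rng.random(400) < 0.5)}
            kappas.append(cohen_kappa(a, b))
        assert abs(float(np.mean(kappas))) < 0.03

    def test_degenerate_single_category_agreement_is_one(self):
        labels = {f"p{i}": False for i in range(10)}
        assert cohen_kappa(labels, dict(labels)) == 1.0


class TestStratifiedReport:
    def test_band_counts_partition_by_age(self):
        labelled = generate(CohortConfig(n_patients=400, seed=3))
        from asthmafinder.definition import classify_cohort
        from asthmafinder.emr import age_in_years

        table = classify_cohort(labelled.cohort)
        algorithm = dict(zip(table.patient_id, table.is_case))
        report = stratified_report(labelled.cohort, algorithm, labelled.gold)
        by_band = {s.label: s for s in report.strata}
        ages = {
            p.patient_id: age_in_years(p.birth_date, labelled.cohort.reference_date)
            for p in labelled.cohort.patients
        }
        n_young = sum(1 for a in ages.values() if 1 <= a <= 2)
        assert by_band["1-17"].n == by_band["3-17"].n + n_young
        assert by_band["1-17"].n >= by_band["3-17"].n >= by_band["6-17"].n

    def test_single_band_equals_unstratified_confusion(self):
        labelled = generate(CohortConfig(n_patients=200, seed=5))
        from asthmafinder.definition import classify_cohort

        table = classify_cohort(labelled.cohort)
        algorithm = dict(zip(table.patient_id, table.is_case))
        report = stratified_report(
            labelled.cohort, algorithm, labelled.gold, age_bands=[(1, 17)]
        )
        eligible = [
            p.patient_id
            for p in labelled.cohort.patients
        ]
        # ages are generated in 1..17, so the single band covers everyone
        cm = build_confusion(algorithm, labelled.gold)
        assert report.strata[0].confusion == cm

    def test_empty_stratum_reports_undefined_metrics_not_exception(self):
        ages = {"a": 5, "b": 9}
        report = report_from_ages(
            ages, {"a": True, "b": False}, {"a": True, "b": False},
            age_bands=[(15, 17)],
        )
        stratum = report.strata[0]
        assert stratum.n == 0
        assert all(est is None for est in stratum.metrics.values())
        df = report.to_dataframe()
        assert math.isnan(df.loc[0, "sensitivity"])

    def test_formatted_table_shows_one_decimal_percentages(self):
        cm = VALIDATION_TABLE[0][1]
        algorithm, gold = _labels_for(cm)
        ages = {pid: 10 for pid in algorithm}
        report = report_from_ages(ages, algorithm, gold, age_bands=[(1, 17)])
        text = report.format_table()
        assert "87.4" in text and "98.6" in text and "91.2" in text and "97.9" in text


@pytest.mark.parametrize(
    "value, expected",
    [(87.45, 87.5), (97.25, 97.3), (91.15, 91.2), (-2.45, -2.5), (87.44, 87.4)],
)
def test_rounding_is_half_away_from_zero(value, expected):
    assert round_half_up(value) == expected
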