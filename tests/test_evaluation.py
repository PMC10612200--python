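"""AUC/DeLong statistics, threshold metrics, Youden point, logistic ORs and
cohort comparison tests."""

import numpy as np
import pytest

from mrfusion.evaluation import (
    DegenerateVarianceError,
    UndefinedAucError,
    cohort_compare,
    delong_test,
    evaluate_models,
    multivariate_logistic,
    roc_auc,
    threshold_metrics,
    youden_threshold,
)
from mrfusion.io_formats import ClinicalRecord


def make_records(n, rng, response=None):
    recs = []
    for i in range(n):
        recs.append(
            ClinicalRecord(
                patient_id=f"P{i}",
                sex="male" if rng.random() < 0.7 else "female",
                age=float(rng.normal(55, 10)),
                cea="positive" if rng.random() < 0.4 else "negative",
                cT=rng.choice(["T2", "T3", "T4"]),
                cN=rng.choice(["N0", "N1", "N2"]),
                response=int(response[i]) if response is not None else int(rng.random() < 0.5),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_pair_counting_example():
    r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert r.auc == pytest.approx(0.75)  # 3 of 4 pos/neg pairs ordered correctly
    assert r.ci95[0] <= r.auc <= r.ci95[1]
    assert 0 <= r.ci95[0] and r.ci95[1] <= 1


def test_auc_perfect_and_all_ties():
    assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0
    assert roc_auc([5.0] * 8, [0, 1] * 4).auc == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(UndefinedAucError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_curve_endpoints_and_monotone(rng):
    scores = rng.normal(size=100)
    labels = rng.integers(0, 2, 100)
    r = roc_auc(scores, labels)
    assert tuple(r.curve[0]) == (0.0, 0.0)
    assert tuple(r.curve[-1]) == (1.0, 1.0)
    assert np.all(np.diff(r.curve[:, 0]) >= 0) and np.all(np.diff(r.curve[:, 1]) >= 0)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, 80)
    a = roc_auc(scores, labels).auc
    b = roc_auc(np.exp(2 * scores) + 5, labels).auc
    assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_and_monotone_scores(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    r = delong_test(scores, scores, labels)
    assert r.p == 1.0 and r.z == 0.0
    r2 = delong_test(scores, np.tanh(scores) * 3 + 1, labels)
    assert r2.p == pytest.approx(1.0)


def test_delong_symmetry(rng):
    a, b = rng.normal(size=100), rng.normal(size=100)
    labels = rng.integers(0, 2, 100)
    r_ab = delong_test(a, b, labels)
    r_ba = delong_test(b, a, labels)
    assert r_ab.p == pytest.approx(r_ba.p)
    assert r_ab.z == pytest.approx(-r_ba.z)


def test_delong_degenerate_variance_error():
    labels = np.array([0, 0, 1, 1])
    # both models separate perfectly but in opposite directions: the
    # difference has zero estimated variance yet the AUCs differ
    with pytest.raises(DegenerateVarianceError):
        delong_test([0, 0, 1, 1], [1, 1, 0, 0], labels)


def test_delong_detects_large_gap(rng):
    n = 200
    labels = np.r_[np.zeros(n), np.ones(n)].astype(int)
    good = np.r_[rng.normal(0, 1, n), rng.normal(2.0, 1, n)]
    noise = rng.normal(size=2 * n)
    r = delong_test(good, noise, labels)
    assert r.p < 1e-6 and r.z > 0


# ---------------------------------------------------------------------------
# threshold metrics


def test_threshold_metrics_hand_counts():
    # TP=3, FP=1, FN=1, TN=3 at threshold 0.5
    scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1]
    labels = [1, 1, 1, 0, 1, 0, 0, 0]
    m = threshold_metrics(scores, labels, 0.5)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(0.75)
    assert m.accuracy == pytest.approx(0.75)
    assert m.counts == {"tp": 3, "fp": 1, "fn": 1, "tn": 3}
    for key in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        lo, hi = m.ci[key]
        assert lo <= hi


def test_threshold_extremes():
    scores = np.linspace(0.1, 0.9, 10)
    labels = np.r_[np.zeros(5), np.ones(5)]
    m_low = threshold_metrics(scores, labels, -1.0)
    assert m_low.sensitivity == 1.0 and m_low.specificity == 0.0
    m_high = threshold_metrics(scores, labels, 2.0)
    assert m_high.sensitivity == 0.0 and m_high.specificity == 1.0
    with pytest.warns(UserWarning):
        assert threshold_metrics(scores, labels, 2.0).ppv is None


def test_threshold_metric_identities(rng):
    scores = rng.random(60)
    labels = rng.integers(0, 2, 60)
    m = threshold_metrics(scores, labels, 0.5)
    n_pos = labels.sum()
    assert m.sensitivity * n_pos + m.counts["fn"] == pytest.approx(n_pos)
    prev = n_pos / 60
    assert m.accuracy == pytest.approx(m.sensitivity * prev + m.specificity * (1 - prev))


# ---------------------------------------------------------------------------
# Youden


def test_youden_exhaustive_example():
    t = youden_threshold([0.2, 0.3, 0.7, 0.9], [0, 0, 1, 1])
    assert 0.3 < t < 0.7  # J = 1 only between 0.3 and 0.7 (midpoint 0.5)
    assert t == pytest.approx(0.5)


def test_youden_lower_tie_break_and_inversion(rng):
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = youden_threshold(scores, labels)
    m = threshold_metrics(scores, labels, t)
    assert m.sensitivity == 1.0 and m.specificity == 1.0
    t_inv = youden_threshold(scores, 1 - labels)
    # inverted labels: no interior threshold helps; optimum is degenerate
    m_inv = threshold_metrics(scores, 1 - labels, t_inv)
    assert m_inv.sensitivity + m_inv.specificity - 1 == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# logistic regression


def test_logistic_or_matches_2x2_cross_product(rng):
    # table (20, 10; 10, 20): OR = (20*20)/(10*10) = 4
    pred = np.r_[np.ones(30), np.zeros(30)].astype(int)
    labels = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)].astype(int)
    df = multivariate_logistic({"model": pred}, None, labels)
    assert df.loc[df.predictor == "model", "odds_ratio"].iloc[0] == pytest.approx(4.0, rel=1e-6)


def test_logistic_null_predictor_ci_covers_one(rng):
    n = 1000
    labels = rng.integers(0, 2, n)
    pred = rng.integers(0, 2, n)  # independent of outcome
    df = multivariate_logistic({"model": pred}, None, labels)
    row = df[df.predictor == "model"].iloc[0]
    assert row.ci_lo < 1.0 < row.ci_hi


def test_logistic_duplicate_predictor_warns(rng):
    labels = rng.integers(0, 2, 100)
    pred = rng.integers(0, 2, 100)
    with pytest.warns(UserWarning, match="rank deficient"):
        multivariate_logistic({"a": pred, "b": pred}, None, labels)


def test_logistic_with_clinical_covariates(rng):
    labels = rng.integers(0, 2, 200)
    recs = make_records(200, rng, response=labels)
    pred = (labels + (rng.random(200) < 0.3)) % 2  # noisy copy of the label
    df = multivariate_logistic({"CFDL": pred}, recs, labels)
    assert set(df.predictor) >= {"CFDL", "sex_male", "age", "cea_positive",
                                 "cT_T3", "cT_T4", "cN_N1", "cN_N2"}
    assert df.loc[df.predictor == "CFDL", "odds_ratio"].iloc[0] > 1.0


def test_logistic_perfect_separation_flagged(rng):
    labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
    pred = labels.copy()  # perfectly separating predictor
    df = multivariate_logistic({"model": pred}, None, labels)
    assert df.penalized.all()


# ---------------------------------------------------------------------------
# cohort comparison


def test_cohort_compare_identical_cohorts(rng):
    recs = make_records(60, rng)
    p = cohort_compare(recs, list(recs))
    for var in ("sex", "cea", "cT", "cN", "response"):
        assert p[var] == pytest.approx(1.0)


def test_cohort_compare_hand_chi2():
    # 2x2 sex table (30, 10; 10, 30): chi2 = 20, p < 0.001
    def rec(sex, i):
        return ClinicalRecord(f"P{i}", sex, 50.0, "negative", "T3", "N1", 0)

    a = [rec("male", i) for i in range(30)] + [rec("female", i) for i in range(10)]
    b = [rec("male", i) for i in range(10)] + [rec("female", i) for i in range(30)]
    from scipy.stats import chi2

    p = cohort_compare(a, b)
    assert p["sex"] == pytest.approx(float(chi2.sf(20.0, 1)), rel=1e-6)
    assert p["sex"] < 0.001


def test_cohort_compare_age_mannwhitney(rng):
    a = make_records(50, rng)
    b = make_records(50, rng)
    for r in b:
        r.age += 15.0
    assert cohort_compare(a, b)["age"] < 0.001


# ---------------------------------------------------------------------------
# report assembly


def test_evaluate_models_delong_matrix_structure(rng):
    labels = rng.integers(0, 2, 80)
    scores = {k: rng.normal(size=80) + labels * s for k, s in
              [("RS", 0.5), ("CFRS", 0.8), ("DL", 1.0), ("CFDL", 1.4)]}
    report = evaluate_models(scores, labels)
    dl = report["delong"]
    names = list(scores)
    for a in names:
        assert dl[a][a] == 1.0
        for b in names:
            assert dl[a][b] == pytest.approx(dl[b][a])
    for name in names:
        entry = report["models"][name]
        assert {"roc", "metrics"} <= set(entry)
        assert 0 <= entry["roc"].auc <= 1
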