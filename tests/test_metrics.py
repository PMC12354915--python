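"""Evaluation metrics against hand arithmetic and independent oracles."""

import numpy as np
import pytest

from apneakit.metrics import (ConfusionCounts, auc, bland_altman,
                              classification_metrics, confusion_counts,
                              icc_absolute_agreement, macro_f1,
                              regression_metrics)


def test_perfect_counts_give_unit_metrics():
    m = classification_metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
    assert all(v == 1.0 for v in m.values())


def test_zero_denominators_reported_as_undefined():
    m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert m["SEN"] is None and m["PPV"] is None and m["F1"] is None
    assert m["ACC"] == 1.0


def test_hand_arithmetic_confusion_example():
    m = classification_metrics(ConfusionCounts(tp=8, tn=5, fp=2, fn=5))
    assert m["ACC"] == pytest.approx(0.65)
    assert m["SEN"] == pytest.approx(0.6154, abs=1e-4)
    assert m["PPV"] == pytest.approx(0.8)
    assert m["F1"] == pytest.approx(0.6957, abs=1e-4)


def test_accuracy_is_prevalence_weighted_mean_of_sen_spe():
    rng = np.random.default_rng(0)
    for _ in range(20):
        tp, tn, fp, fn = rng.integers(1, 50, 4)
        m = classification_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        prev = (tp + fn) / (tp + tn + fp + fn)
        assert m["ACC"] == pytest.approx(prev * m["SEN"] + (1 - prev) * m["SPE"])
        assert min(m["SEN"], m["SPE"]) <= m["ACC"] <= max(m["SEN"], m["SPE"])


def test_macro_f1_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(1)
    y, p = rng.integers(0, 4, 200), rng.integers(0, 4, 200)
    assert macro_f1(y, p, classes=(0, 1, 2, 3)) == pytest.approx(
        sk.f1_score(y, p, average="macro"), abs=1e-12)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_separated_and_three_point_rank_oracle():
    assert auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0
    assert auc(np.array([0.1, 0.5, 0.9]), np.array([0, 1, 1])) == 1.0


def test_auc_null_simulation_near_half():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=10_000)
    labels = rng.integers(0, 2, 10_000)
    assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)


def test_auc_invariant_under_monotone_transform_and_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(3)
    scores = rng.normal(size=500)
    labels = (scores + rng.normal(0, 1.5, 500) > 0).astype(int)
    a = auc(scores, labels)
    assert auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
    assert auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)
    assert a == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)


def test_auc_ties_get_half_credit_and_single_class_errors():
    assert auc(np.array([0.5, 0.5]), np.array([0, 1])) == 0.5
    with pytest.raises(ValueError):
        auc(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Regression agreement
# ---------------------------------------------------------------------------

def test_perfect_prediction_regression_metrics():
    t = np.array([5.0, 10.0, 20.0, 40.0])
    m = regression_metrics(t, t)
    assert m["R2"] == 1.0 and m["MAE"] == 0.0
    assert m["ICC"] == pytest.approx(1.0)


def test_mean_prediction_gives_zero_r2():
    t = np.array([10.0, 20.0, 30.0])
    m = regression_metrics(t, np.full(3, t.mean()))
    assert m["R2"] == pytest.approx(0.0)


def test_hand_arithmetic_regression_example():
    m = regression_metrics(np.array([10.0, 20.0, 30.0]),
                           np.array([12.0, 18.0, 33.0]))
    assert m["MAE"] == pytest.approx(7 / 3)
    assert m["R2"] == pytest.approx(1 - 17 / 200)


def test_r2_matches_streaming_oracle_to_1e12():
    rng = np.random.default_rng(4)
    t = rng.uniform(0, 60, 300)
    p = t + rng.normal(0, 5, 300)
    # independent single-pass accumulation of SSE and SST
    n = s = s2 = sse = 0.0
    for ti in t:
        n += 1
        s += ti
        s2 += ti * ti
    for ti, pi in zip(t, p):
        sse += (ti - pi) ** 2
    sst = s2 - s * s / n
    want = 1 - sse / sst
    assert regression_metrics(t, p)["R2"] == pytest.approx(want, abs=1e-12)


def test_zero_variance_targets_error():
    with pytest.raises(ValueError, match="variance"):
        regression_metrics(np.array([5.0, 5.0, 5.0]), np.array([4.0, 5.0, 6.0]))


def test_icc_agrees_with_direct_anova_formula():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 60, 50)
    b = a + rng.normal(0, 4, 50)
    icc = icc_absolute_agreement(a, b)
    # two-way absolute-agreement single-measure ICC from mean squares
    n, k = len(a), 2
    data = np.stack([a, b], axis=1)
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (((data - data.mean(axis=1, keepdims=True)
             - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
           / ((n - 1) * (k - 1)))
    want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert icc == pytest.approx(want, abs=1e-9)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def test_bland_altman_identical_and_offset_arrays():
    t = np.array([1.0, 2.0, 3.0])
    assert bland_altman(t, t) == {"mean_diff": 0.0, "loa_low": 0.0,
                                  "loa_high": 0.0}
    m = bland_altman(t, t + 2.0)
    assert m["mean_diff"] == pytest.approx(2.0)
    assert m["loa_high"] - m["loa_low"] == pytest.approx(0.0)


def test_bland_altman_hand_example():
    t = np.zeros(4)
    p = np.array([1.0, -1.0, 3.0, -3.0])
    m = bland_altman(t, p)
    assert m["mean_diff"] == pytest.approx(0.0)
    assert m["loa_high"] == pytest.approx(1.96 * 2.582, abs=2e-3)
    assert m["loa_low"] == pytest.approx(-1.96 * 2.582, abs=2e-3)
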