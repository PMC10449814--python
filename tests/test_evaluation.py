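"""Confusion matrix, P/R/F1, OA, kappa, mIoU, and the paired t-test."""

import numpy as np
import pytest
from scipy import stats

from savseg.evaluation import (ConfusionMatrix, confusion_matrix, miou,
                               miou_from_confusion, paired_f1_test,
                               per_class_prf, summary_metrics)


def _brute_force_cm(truth, pred, k):
    cm = np.zeros((k, k), dtype=int)
    for r in range(truth.shape[0]):
        for c in range(truth.shape[1]):
            cm[truth[r, c], pred[r, c]] += 1
    return cm


def test_confusion_diagonal_for_perfect_prediction(rng):
    mask = rng.integers(0, 3, (16, 16))
    cm = confusion_matrix(mask, mask, 3)
    assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)
    assert cm.total == mask.size


def test_confusion_toy_example():
    truth = np.array([[0, 0], [1, 1]])
    pred = np.array([[0, 1], [1, 1]])
    cm = confusion_matrix(truth, pred, 2)
    assert np.array_equal(cm.counts, [[1, 1], [0, 2]])


def test_confusion_matches_nested_loop_oracle(rng):
    truth = rng.integers(0, 5, (64, 64))
    pred = rng.integers(0, 5, (64, 64))
    cm = confusion_matrix(truth, pred, 5)
    assert np.array_equal(cm.counts, _brute_force_cm(truth, pred, 5))
    # conservation: row sums = truth counts, col sums = prediction counts
    assert np.array_equal(cm.counts.sum(axis=1), np.bincount(truth.ravel(), minlength=5))
    assert np.array_equal(cm.counts.sum(axis=0), np.bincount(pred.ravel(), minlength=5))


def test_confusion_rejects_bad_inputs():
    with pytest.raises(ValueError):
        confusion_matrix(np.zeros((2, 2), int), np.zeros((3, 2), int), 2)
    with pytest.raises(ValueError):
        confusion_matrix(np.array([[5]]), np.array([[0]]), 2)


def test_prf_perfect_diagonal():
    cm = ConfusionMatrix(np.diag([5, 3, 2]))
    p, r, f1, flags = per_class_prf(cm)
    assert (p == 1).all() and (r == 1).all() and (f1 == 1).all()
    assert not flags.any()


def test_prf_never_predicted_class_is_zero_and_flagged():
    cm = ConfusionMatrix(np.array([[4, 0], [2, 0]]))
    p, r, f1, flags = per_class_prf(cm)
    assert p[1] == 0 and f1[1] == 0 and flags[1]


def test_prf_worked_example():
    cm = ConfusionMatrix(np.array([[1, 1], [0, 2]]))
    p, r, f1, _ = per_class_prf(cm)
    np.testing.assert_allclose(p, [1.0, 2 / 3])
    np.testing.assert_allclose(r, [0.5, 1.0])
    np.testing.assert_allclose(f1, [2 / 3, 0.8])


def test_summary_perfect_prediction():
    rep = summary_metrics(ConfusionMatrix(np.diag([7, 5])))
    assert rep.overall_accuracy == 1.0
    assert rep.kappa == pytest.approx(1.0)
    assert rep.mean_f1 == 1.0 and rep.miou == 1.0


def test_kappa_zero_for_chance_level_prediction():
    # rank-1 cm: prediction statistically independent of truth
    row = np.array([0.6, 0.4])
    col = np.array([0.3, 0.7])
    cm = ConfusionMatrix((np.outer(row, col) * 1000).astype(int))
    rep = summary_metrics(ConfusionMatrix(np.outer(row, col) * 1000))
    assert abs(rep.kappa) < 1e-12


def test_summary_worked_example():
    rep = summary_metrics(ConfusionMatrix(np.array([[1, 1], [0, 2]])))
    assert rep.overall_accuracy == pytest.approx(0.75)
    pe = (2 * 1 + 2 * 3) / 16
    assert rep.kappa == pytest.approx((0.75 - pe) / (1 - pe), abs=1e-12)
    assert rep.mean_f1 == pytest.approx((2 / 3 + 0.8) / 2, abs=1e-12)


def test_kappa_bounded_by_overall_accuracy(rng):
    for _ in range(20):
        cm = ConfusionMatrix(rng.integers(0, 50, (4, 4)))
        if cm.total == 0:
            continue
        rep = summary_metrics(cm)
        assert rep.kappa <= rep.overall_accuracy + 1e-12


def test_miou_dual_route_agreement(rng):
    truth = rng.integers(0, 4, (32, 32))
    pred = rng.integers(0, 4, (32, 32))
    from_masks = miou(truth, pred, 4)
    from_cm = miou_from_confusion(confusion_matrix(truth, pred, 4))
    assert from_masks == pytest.approx(from_cm, abs=1e-12)


def test_miou_trivial_cases(rng):
    mask = rng.integers(0, 3, (8, 8))
    assert miou(mask, mask, 3) == 1.0
    ones = np.zeros((8, 8), int)
    assert miou(ones, ones, 5) == 1.0  # absent classes excluded from the mean


def test_miou_binary_disjoint_regions():
    truth = np.zeros((4, 4), int)
    truth[:2] = 1
    pred = np.zeros((4, 4), int)
    pred[2:] = 1
    # oracle: explicit pixel-set operations
    iou0 = 0 / 16  # class 0: intersection empty? rows 2,3 truth=0, pred rows 0,1 =0
    inter0 = np.logical_and(truth == 0, pred == 0).sum()
    union0 = np.logical_or(truth == 0, pred == 0).sum()
    inter1 = np.logical_and(truth == 1, pred == 1).sum()
    union1 = np.logical_or(truth == 1, pred == 1).sum()
    expected = 0.5 * (inter0 / union0 + inter1 / union1)
    assert miou(truth, pred, 2) == pytest.approx(expected, abs=1e-12)


def test_f1_harmonic_mean_bounds(rng):
    for _ in range(30):
        cm = ConfusionMatrix(rng.integers(0, 40, (3, 3)))
        p, r, f1, _ = per_class_prf(cm)
        assert (f1 <= np.maximum(p, r) + 1e-12).all()
        # symmetry of the harmonic mean
        np.testing.assert_allclose(f1, np.where(p + r > 0, 2 * r * p / np.where(p + r > 0, p + r, 1), 0))


def test_paired_t_test_matches_textbook_formula(rng):
    a = rng.random(16)
    b = rng.random(16)
    t, p, df = paired_f1_test(a, b)
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(16))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 15)
    assert t == pytest.approx(t_oracle, abs=1e-9)
    assert p == pytest.approx(p_oracle, abs=1e-9)
    assert df == 15


def test_paired_t_test_degenerate_cases(rng):
    a = rng.random(8)
    with pytest.raises(ValueError, match="zero variance"):
        paired_f1_test(a, a)
    with pytest.raises(ValueError, match="zero variance"):
        paired_f1_test(a, a + 0.1)  # constant shift -> zero-variance differences
    with pytest.raises(ValueError):
        paired_f1_test([0.1, 0.2], [0.3, 0.1])
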