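"""Accuracy assessment: confusion matrix, per-class P/R/F1, overall accuracy,
Cohen's kappa, mIoU, and paired t-tests across model configurations.

Conventions: the confusion matrix is stored with rows = true labels and
columns = predicted labels.  F1 = 2 P R / (P + R); any 0/0 is defined as 0
and flagged.  mIoU averages O_i / U_i over classes, where O_i is the true
positives of class i and U_i = TP + FP + FN; classes absent from both masks
(U_i = 0) are excluded from the mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "per_class_prf", "summary_metrics", "miou", "miou_from_confusion",
           "paired_f1_test"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int, rows = truth, cols = prediction

    @property
    def n_classes(self):
        return self.counts.shape[0]

    @property
    def total(self):
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    degenerate: np.ndarray     # classes where a 0/0 convention was applied
    mean_f1: float
    overall_accuracy: float
    kappa: float
    miou: float

    def to_dict(self):
        return {
            "per_class": [
                {"class": int(i), "precision": float(p), "recall": float(r),
                 "f1": float(f), "degenerate": bool(d)}
                for i, (p, r, f, d) in enumerate(
                    zip(self.precision, self.recall, self.f1, self.degenerate))],
            "mean_f1": self.mean_f1,
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "miou": self.miou,
        }

    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            lines = ["class,precision,recall,f1,degenerate"]
            for row in self.to_dict()["per_class"]:
                lines.append(f"{row['class']},{row['precision']:.6f},"
                             f"{row['recall']:.6f},{row['f1']:.6f},{row['degenerate']}")
            lines.append(f"mean_f1,,,{self.mean_f1:.6f},")
            lines.append(f"overall_accuracy,,,{self.overall_accuracy:.6f},")
            lines.append(f"kappa,,,{self.kappa:.6f},")
            lines.append(f"miou,,,{self.miou:.6f},")
            path.write_text("\n".join(lines) + "\n")


def _check_pair(truth, pred, n_classes):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"masks not co-registered: {truth.shape} vs {pred.shape}")
    for name, m in (("truth", truth), ("prediction", pred)):
        if m.size and (m.min() < 0 or m.max() >= n_classes):
            raise ValueError(f"{name} mask has labels outside [0, {n_classes})")
    return truth, pred


def confusion_matrix(truth, pred, n_classes: int) -> ConfusionMatrix:
    truth, pred = _check_pair(truth, pred, n_classes)
    counts = np.bincount(truth.ravel() * n_classes + pred.ravel(),
                         minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def per_class_prf(cm: ConfusionMatrix):
    """(precision, recall, f1, degenerate-flags) per class; 0/0 -> 0."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    colsum = c.sum(axis=0)
    rowsum = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, tp / colsum, 0.0)
        recall = np.where(rowsum > 0, tp / rowsum, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    degenerate = (colsum == 0) | (rowsum == 0)
    return precision, recall, f1, degenerate


def miou_from_confusion(cm: ConfusionMatrix) -> float:
    """mIoU from confusion counts; classes with empty union are excluded."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    union = c.sum(axis=0) + c.sum(axis=1) - tp
    present = union > 0
    if not present.any():
        raise ValueError("no class present in either mask")
    return float((tp[present] / union[present]).mean())


def miou(truth, pred, n_classes: int) -> float:
    """mIoU computed directly from masks via per-class pixel-set operations
    (independent of the confusion-matrix route)."""
    truth, pred = _check_pair(truth, pred, n_classes)
    ious = []
    for k in range(n_classes):
        t = truth == k
        p = pred == k
        union = np.logical_or(t, p).sum()
        if union == 0:
            continue
        ious.append(np.logical_and(t, p).sum() / union)
    if not ious:
        raise ValueError("no class present in either mask")
    return float(np.mean(ious))


def summary_metrics(cm: ConfusionMatrix, exclude_background: bool = False,
                    background_id: int = 0) -> MetricsReport:
    """All headline metrics from one confusion matrix.

    ``mean_f1`` averages over every class by default; pass
    ``exclude_background=True`` to drop the background class from the mean
    (per-class values are always reported for all classes).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, f1, degenerate = per_class_prf(cm)
    report_set = np.ones(cm.n_classes, dtype=bool)
    if exclude_background:
        report_set[background_id] = False
    c = cm.counts.astype(np.float64)
    total = c.sum()
    oa = float(np.trace(c) / total)
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum() / total ** 2)
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return MetricsReport(
        precision=precision, recall=recall, f1=f1, degenerate=degenerate,
        mean_f1=float(f1[report_set].mean()),
        overall_accuracy=oa, kappa=float(kappa),
        miou=miou_from_confusion(cm))


def paired_f1_test(f1_a, f1_b):
    """Paired two-sided t-test on per-class F1 vectors -> (t, p, df)."""
    a = np.asarray(f1_a, dtype=np.float64)
    b = np.asarray(f1_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired vectors")
    n = a.size
    if n < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("differences have zero variance; paired t-test degenerate")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), n - 1
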