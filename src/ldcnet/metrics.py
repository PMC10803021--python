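"""Confusion-matrix metric suite: precision, recall, F1 and mIoU.

All metrics derive from a single (k+1) x (k+1) pixel confusion matrix M with
M[i, j] = pixels of true class i predicted as class j, accumulated globally
over a split (elementwise sum of per-image matrices), so dataset-level
results are invariant to how images are batched.  Per class c:

    TP = M[c, c]        FN = row_c - TP        FP = col_c - TP
    precision = TP / (TP + FP)     recall = TP / (TP + FN)
    F1 = 2 P R / (P + R) = 2 TP / (2 TP + FP + FN)
    IoU = TP / (TP + FP + FN)

Macro means average over the k+1 classes (background included).  A class
absent from both prediction and truth (TP + FP + FN = 0) has no defined
score and is excluded from the macro averages; its per-class entries are
NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def confusion_matrix(pred, true, k: int) -> np.ndarray:
    """Exact (k+1)x(k+1) pixel counts; raises on shape/label violations."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth shapes differ")
    n = k + 1
    for name, m in (("pred", pred), ("true", true)):
        if m.size and (m.min() < 0 or m.max() > k):
            raise ValueError(f"{name} labels outside 0..{k}")
    idx = true.astype(np.int64).ravel() * n + pred.astype(np.int64).ravel()
    return np.bincount(idx, minlength=n * n).reshape(n, n)


def _tp_fp_fn(cm):
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return tp, fp, fn


def _safe_div(num, den):
    out = np.full_like(num, np.nan, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def precision_recall_f1(cm):
    """Per-class and macro precision / recall / F1 from a confusion matrix."""
    tp, fp, fn = _tp_fp_fn(cm)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    with np.errstate(invalid="ignore"):
        return {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "mean_precision": float(np.nanmean(precision)),
            "mean_recall": float(np.nanmean(recall)),
            "mean_f1": float(np.nanmean(f1)),
        }


def per_class_iou(cm) -> np.ndarray:
    tp, fp, fn = _tp_fp_fn(cm)
    return _safe_div(tp, tp + fp + fn)


def mean_iou(cm) -> float:
    """Mean over classes of TP / (TP + FP + FN); absent classes excluded."""
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(per_class_iou(cm)))


@dataclass
class MetricsReport:
    """Full per-class + macro metric bundle for one confusion matrix."""

    confusion: np.ndarray
    per_class: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm):
        cm = np.asarray(cm)
        prf = precision_recall_f1(cm)
        iou = per_class_iou(cm)
        per_class = {
            "precision": prf["precision"].tolist(),
            "recall": prf["recall"].tolist(),
            "f1": prf["f1"].tolist(),
            "iou": iou.tolist(),
        }
        with np.errstate(invalid="ignore"):
            means = {
                "precision": prf["mean_precision"],
                "recall": prf["mean_recall"],
                "f1": prf["mean_f1"],
                "miou": float(np.nanmean(iou)),
            }
        return cls(confusion=cm, per_class=per_class, means=means)

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "means": self.means,
        }, indent=2)

    def to_csv_rows(self):
        rows = [["class", "precision", "recall", "f1", "iou"]]
        n = len(self.per_class["iou"])
        for c in range(n):
            rows.append([str(c)] + [
                f"{self.per_class[m][c]:.6f}" for m in
                ("precision", "recall", "f1", "iou")])
        rows.append(["mean",
                     f"{self.means['precision']:.6f}",
                     f"{self.means['recall']:.6f}",
                     f"{self.means['f1']:.6f}",
                     f"{self.means['miou']:.6f}"])
        return rows
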