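"""Evaluation metrics for joint lesion segmentation and malignancy diagnosis.

Classification metrics are computed from a confusion-count quadruple with
the malignant class as positive; ratios with a zero denominator are
reported as 0 and flagged.  AUPRC integrates precision step-wise
(rectangles) over recall, grouping tied scores.  Segmentation metrics come
from the 2-class (lesion / background) pixel confusion matrix

    p_ij = number of pixels of class i predicted as class j,

from which overall accuracy and the class-averaged accuracy / IoU / Dice /
precision / recall follow.  Dataset-level values average per-image metrics
(not pooled pixel counts) by default; a class absent from an image is
skipped from that image's class mean and flagged.  The module also carries
the small report-arithmetic helpers (metric deltas, macro-F1 from
per-class precision/recall, percentage formatting) used when comparing
printed result tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "classification_metrics", "macro_f1_from_pr", "auprc",
    "confusion_from_masks", "segmentation_metrics_from_confusion",
    "segmentation_metrics", "table_delta", "format_percent",
]

LESION, BACKGROUND = 0, 1  # class indices of the 2-class pixel confusion


@dataclass(frozen=True)
class ConfusionCounts:
    """Image-level counts with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and false-negative rate from counts."""
    flags: list = []
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    out = {
        "accuracy": (tp + tn) / counts.total,
        "precision": _ratio(tp, tp + fp, flags, "precision"),
        "recall": _ratio(tp, tp + fn, flags, "recall"),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn, flags, "f1"),
        "fnr": _ratio(fn, fn + tp, flags, "fnr"),
    }
    out["undefined"] = flags
    return out


def macro_f1_from_pr(prec_pos: float, rec_pos: float,
                     prec_neg: float, rec_neg: float) -> float:
    """Unweighted mean of per-class F1 (harmonic mean of precision/recall)."""
    for v in (prec_pos, rec_pos, prec_neg, rec_neg):
        if not 0.0 <= v <= 1.0:
            raise ValueError("precision/recall values must lie in [0, 1]")

    def f1(p, r):
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    return 0.5 * (f1(prec_pos, rec_pos) + f1(prec_neg, rec_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise over recall.

    Scores are ranked descending; tied scores form a single threshold group,
    and each group's rectangle contributes (delta recall) * precision-at-
    threshold.  Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPRC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


# ------------------------------------------------------------- segmentation
def confusion_from_masks(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """2x2 pixel confusion p_ij (rows: true class, cols: predicted class).

    Class 0 is lesion (foreground), class 1 background.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    if not np.isin(pred, (0, 1)).all() or not np.isin(gt, (0, 1)).all():
        raise ValueError("masks must be binary")
    p = np.zeros((2, 2), dtype=np.int64)
    fg_t, fg_p = gt == 1, pred == 1
    p[LESION, LESION] = np.count_nonzero(fg_t & fg_p)
    p[LESION, BACKGROUND] = np.count_nonzero(fg_t & ~fg_p)
    p[BACKGROUND, LESION] = np.count_nonzero(~fg_t & fg_p)
    p[BACKGROUND, BACKGROUND] = np.count_nonzero(~fg_t & ~fg_p)
    return p


def segmentation_metrics_from_confusion(p: np.ndarray) -> dict:
    """oAcc and class-mean accuracy/IoU/Dice/precision/recall from one p_ij.

    Per-class ratios whose denominator is zero (class absent from ground
    truth and/or prediction) are skipped from the class mean and flagged.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (2, 2) or (p < 0).any() or p.sum() == 0:
        raise ValueError("p must be a nonnegative 2x2 matrix with positive sum")
    flags: list = []
    row = p.sum(axis=1)      # ground-truth pixels per class
    col = p.sum(axis=0)      # predicted pixels per class
    diag = np.diag(p)

    def class_mean(nums, dens, name):
        vals = [n / d for n, d in zip(nums, dens) if d > 0]
        if len(vals) < 2:
            flags.append(name)
        return float(np.mean(vals)) if vals else 0.0

    union = row + col - diag
    out = {
        "oAcc": float(diag.sum() / p.sum()),
        "mAcc": class_mean(diag, row, "mAcc"),
        "mIoU": class_mean(diag, union, "mIoU"),
        "mDice": class_mean(2 * diag, row + col, "mDice"),
        "mPrec": class_mean(diag, col, "mPrec"),
        "mRecall": class_mean(diag, row, "mRecall"),
    }
    out["undefined"] = flags
    return out


_SEG_KEYS = ("oAcc", "mAcc", "mIoU", "mDice", "mPrec", "mRecall")


def segmentation_metrics(pred_masks, gt_masks, mode: str = "per_image") -> dict:
    """Dataset segmentation metrics from parallel lists of binary masks.

    ``per_image`` (default) computes each image's metrics from its own
    confusion matrix and averages across images; ``pooled`` sums all pixel
    confusions first.  Returns the six summary values, any flags, and the
    per-image breakdown.
    """
    if isinstance(pred_masks, np.ndarray) and pred_masks.ndim == 2:
        pred_masks, gt_masks = [pred_masks], [gt_masks]
    if len(pred_masks) != len(gt_masks) or not len(pred_masks):
        raise ValueError("need equal, nonzero numbers of prediction/truth masks")
    if mode not in ("per_image", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    confs = [confusion_from_masks(pm, gm) for pm, gm in zip(pred_masks, gt_masks)]
    if mode == "pooled":
        out = segmentation_metrics_from_confusion(np.sum(confs, axis=0))
        out["per_image"] = []
        return out
    per_image = [segmentation_metrics_from_confusion(c) for c in confs]
    out = {k: float(np.mean([m[k] for m in per_image])) for k in _SEG_KEYS}
    out["undefined"] = sorted({f for m in per_image for f in m["undefined"]})
    out["per_image"] = per_image
    return out


# ------------------------------------------------------------------ reports
def table_delta(a: float, b: float) -> float:
    """Difference a - b of two values of the same metric on the same scale."""
    return a - b


def format_percent(value: float, decimals: int) -> str:
    """Format a [0,1] metric as a percentage string with fixed decimals."""
    return f"{100.0 * value:.{decimals}f}"
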