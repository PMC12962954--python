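"""Cooperative multi-task objective.

The segmentation branch is supervised by pixel binary cross-entropy plus a
soft (probabilistic) IoU term that directly targets region overlap; the
classification branch by binary cross-entropy on the scalar malignancy
logit.  The total objective is the affine combination

    L_seg   = lambda_bce * L_bce + lambda_iou * L_iou
    L_total = lambda_seg * L_seg + lambda_cls * L_cls

with defaults lambda_bce = 1.0, lambda_iou = 2.0, lambda_seg = 1.0,
lambda_cls = 1.8.  The two-class diagnosis uses the sigmoid/binary form
throughout (a single real logit), not a 2-way softmax.  No class
re-weighting is applied; imbalance is handled upstream by stratified
splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossWeights", "LossReport", "bce_loss", "soft_iou_loss",
           "cls_loss", "total_loss", "combined_loss"]


@dataclass(frozen=True)
class LossWeights:
    bce: float = 1.0
    iou: float = 2.0
    seg: float = 1.0
    cls: float = 1.8

    def validate(self):
        if min(self.bce, self.iou, self.seg, self.cls) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    l_bce: float
    l_iou: float
    l_seg: float
    l_cls: float
    l_total: float
    n_pixels: int


def _check_binary(targets: np.ndarray):
    if not np.isin(targets, (0, 1)).all():
        raise ValueError("targets must be binary (0/1)")


def bce_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean pixel binary cross-entropy, in the stabilized log-sum-exp form

    max(z,0) - z*y + log(1 + exp(-|z|)).
    """
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.shape != logits.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {targets.shape}")
    _check_binary(targets)
    y = Tensor(targets)
    absz = logits.relu() + (-logits).relu()
    per_pixel = logits.relu() - logits * y + (1.0 + (-absz).exp()).log()
    return per_pixel.mean()


def soft_iou_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """1 - (sum p*y) / (sum p + y - p*y), with p = sigmoid(z).  In [0, 1].

    Degenerate case (empty target and a numerically-zero prediction, so the
    denominator vanishes; union below 1e-12 since a sigmoid is never exactly
    0) is defined as 0 with a warning.
    """
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.shape != logits.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {targets.shape}")
    _check_binary(targets)
    p = logits.sigmoid()
    y = Tensor(targets)
    inter = (p * y).sum()
    union = (p + y - p * y).sum()
    if union.item() < 1e-12:
        warnings.warn("soft IoU undefined (empty target and prediction); "
                      "defined as 0", RuntimeWarning, stacklevel=2)
        return Tensor(0.0)
    return 1.0 - inter / union


def cls_loss(q: Tensor, y_cls: int) -> Tensor:
    """Binary cross-entropy on the scalar malignancy logit."""
    q = as_tensor(q)
    if int(y_cls) not in (0, 1):
        raise ValueError("class label must be 0 or 1")
    return bce_loss(q.reshape(1), np.array([float(y_cls)]))


def combined_loss(l_bce: Tensor, l_iou: Tensor, l_cls: Tensor,
                  weights: LossWeights = LossWeights(),
                  n_pixels: int = 0) -> tuple[Tensor, LossReport]:
    """Affine combination as a differentiable Tensor plus a float report."""
    weights.validate()
    l_seg = weights.bce * l_bce + weights.iou * l_iou
    l_tot = weights.seg * l_seg + weights.cls * l_cls
    report = LossReport(
        l_bce=float(as_tensor(l_bce).item()), l_iou=float(as_tensor(l_iou).item()),
        l_seg=float(as_tensor(l_seg).item()), l_cls=float(as_tensor(l_cls).item()),
        l_total=float(as_tensor(l_tot).item()), n_pixels=int(n_pixels))
    return l_tot, report


def total_loss(parts: dict, weights: LossWeights = LossWeights()) -> LossReport:
    """Float-only combination from a ``{'bce':, 'iou':, 'cls':}`` dict."""
    _, report = combined_loss(
        Tensor(float(parts["bce"])), Tensor(float(parts["iou"])),
        Tensor(float(parts["cls"])), weights, n_pixels=parts.get("n", 0))
    return report
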