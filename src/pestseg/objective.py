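"""Training loss (weighted soft-IoU + weighted BCE) and evaluation metrics.

The compound loss ``total_loss = iou_loss + bce_loss`` supervises the
probability map globally (region overlap) and locally (per-pixel
likelihood).  Both terms accept an optional per-pixel weight map; by
default all weights are 1.  Evaluation uses pixel confusion counts with
``ACC = TP / (TP + FN)`` — the recall-form accuracy this model family is
reported with — and the Jaccard index ``IoU = TP / (TP + FP + FN)``.
The conventional ``(TP + TN) / total`` is exposed separately as
:func:`pixel_accuracy` and never silently substituted.

Loss functions are polymorphic: on plain arrays they return a float; on
autodiff tensors they return a scalar tensor usable for backprop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "ConfusionCounts",
    "weighted_iou_loss",
    "weighted_bce_loss",
    "total_loss",
    "boundary_weight_map",
    "confusion_from_masks",
    "accuracy",
    "iou",
    "pixel_accuracy",
    "EPS",
]

EPS = 1e-7  # probability clipping bound for the cross-entropy term


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _prepare(pred, target, w):
    """Lift inputs to tensors; remember whether the caller passed arrays."""
    was_array = not isinstance(pred, Tensor)
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {t.shape}")
    if w is None:
        wt = Tensor(np.ones_like(t.data))
    else:
        wt = w if isinstance(w, Tensor) else Tensor(np.asarray(w, dtype=np.float64))
        if np.any(wt.data < 0):
            raise ValueError("weights must be non-negative")
        if wt.shape != t.shape:
            raise ValueError(f"weight shape {wt.shape} != target shape {t.shape}")
    return p, t, wt, was_array


def weighted_iou_loss(pred, target, w=None):
    """Soft Jaccard loss ``1 - sum(w p t) / sum(w (p + t - p t))``.

    Zero exactly when the prediction reproduces a binary target on all
    positively weighted pixels, one when a binary prediction and target
    are disjoint.  An empty union (both maps identically zero) is defined
    as loss 0, with a warning, since there is nothing to overlap.
    """
    p, t, wt, was_array = _prepare(pred, target, w)
    union_val = float(np.sum(wt.data * (p.data + t.data - p.data * t.data)))
    if union_val == 0.0:
        warnings.warn("empty union: target and prediction are both all-zero; IoU loss defined as 0")
        return 0.0 if was_array else Tensor(0.0)
    inter = (wt * p * t).sum()
    union = (wt * (p + t - p * t)).sum()
    loss = 1.0 - inter / union
    return loss.item() if was_array else loss


def weighted_bce_loss(pred, target, w=None):
    """Weighted mean binary cross-entropy, predictions clipped to [eps, 1-eps]."""
    p, t, wt, was_array = _prepare(pred, target, w)
    pc = T.clip(p, EPS, 1.0 - EPS)
    ll = t * T.log(pc) + (1.0 - t) * T.log(1.0 - pc)
    wsum = float(wt.data.sum())
    if wsum == 0.0:
        raise ValueError("weight map sums to zero")
    loss = (wt * (-1.0 * ll)).sum() * (1.0 / wsum)
    return loss.item() if was_array else loss


def total_loss(pred, target, w=None):
    """Compound loss: soft-IoU term plus BCE term, equally weighted."""
    a = weighted_iou_loss(pred, target, w)
    b = weighted_bce_loss(pred, target, w)
    return a + b


def boundary_weight_map(target: np.ndarray, lam: float = 5.0) -> np.ndarray:
    """Edge-emphasis weights ``1 + lam * |mean3x3(target) - target|``.

    Pixels near the foreground boundary (where the 3x3 local mean of the
    binary mask disagrees with the pixel) receive up to ``1 + lam`` times
    the weight of interior pixels, steering the loss toward object edges.
    """
    t = np.asarray(target, dtype=np.float64)
    local = uniform_filter(t, size=3, mode="nearest")
    return 1.0 + lam * np.abs(local - t)


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary mask comparison; TP+FP+FN+TN = total pixels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_from_masks(pred_mask: np.ndarray, target: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two equal-shape binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    for name, m in (("pred", p), ("target", t)):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} mask is not binary; values {vals[:8]}")
    p = p.astype(bool)
    t = t.astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(c: ConfusionCounts) -> float:
    """Detection accuracy in its recall form, ``TP / (TP + FN)``."""
    denom = c.tp + c.fn
    if denom == 0:
        raise ZeroDivisionError("accuracy undefined: no positive target pixels")
    return c.tp / denom


def iou(c: ConfusionCounts) -> float:
    """Jaccard index ``TP / (TP + FP + FN)`` over pixels."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ZeroDivisionError("IoU undefined: no positive pixels in either mask")
    return c.tp / denom


def pixel_accuracy(c: ConfusionCounts) -> float:
    """Conventional accuracy ``(TP + TN) / total`` — not the reported ACC."""
    if c.total == 0:
        raise ZeroDivisionError("pixel accuracy undefined on empty masks")
    return (c.tp + c.tn) / c.total
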