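"""Soft Dice loss for training on small, imbalanced targets.

The default follows the printed formula exactly: the stabilizing constant
epsilon is added once in the numerator and once in the denominator,

    loss = 1 - 2 * (|GT . Pred| + eps) / (|GT| + |Pred| + eps)

which makes the degenerate empty/empty case evaluate to 1 - 2*eps/eps = -1.
``symmetric_eps=True`` switches to (2*|GT . Pred| + eps) / (|GT| + |Pred| + eps),
for which empty/empty gives loss 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["DiceLossSpec", "dice_loss", "dice_loss_tensor"]


@dataclass(frozen=True)
class DiceLossSpec:
    epsilon: float = 1e-6
    symmetric_eps: bool = False
    reduction: str = "batch-mean"  # "per-sample" or "batch-mean"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.reduction not in ("per-sample", "batch-mean"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


def _dice_terms(inter: float, gt_sum: float, pred_sum: float, spec: DiceLossSpec) -> float:
    eps = spec.epsilon
    if spec.symmetric_eps:
        return 1.0 - (2.0 * inter + eps) / (gt_sum + pred_sum + eps)
    return 1.0 - 2.0 * (inter + eps) / (gt_sum + pred_sum + eps)


def dice_loss(gt: np.ndarray, pred: np.ndarray, spec: DiceLossSpec | None = None) -> float | np.ndarray:
    """Dice loss on numpy arrays (soft intersection: sum of gt * pred).

    ``gt`` must be binary, ``pred`` a probability map in [0, 1] of the same
    shape. Inputs may be single images (H, W) or batches (N, ...); batches
    reduce per spec.reduction.
    """
    spec = spec or DiceLossSpec()
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    if not np.isin(gt, (0.0, 1.0)).all():
        raise ValueError("gt must be binary {0,1}")
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValueError("pred must lie in [0,1]")

    if gt.ndim <= 2:
        inter = float((gt * pred).sum())
        return _dice_terms(inter, float(gt.sum()), float(pred.sum()), spec)

    axes = tuple(range(1, gt.ndim))
    inter = (gt * pred).sum(axis=axes)
    losses = np.array([
        _dice_terms(i, g, p, spec)
        for i, g, p in zip(inter, gt.sum(axis=axes), pred.sum(axis=axes))
    ])
    if spec.reduction == "per-sample":
        return losses
    return float(losses.mean())


def dice_loss_tensor(gt: np.ndarray, pred: Tensor, spec: DiceLossSpec | None = None) -> Tensor:
    """Differentiable batched Dice loss for training.

    ``pred`` is a (N, 1, H, W) probability tensor on the autodiff graph;
    ``gt`` a matching binary array. Returns a scalar tensor (batch mean) or
    a per-sample vector per spec.reduction.
    """
    spec = spec or DiceLossSpec()
    gt_arr = np.asarray(gt, dtype=np.float32).reshape(pred.shape)
    gt_t = Tensor(gt_arr)
    axes = tuple(range(1, len(pred.shape)))
    inter = (gt_t * pred).sum(axis=axes)
    gt_sum = gt_t.sum(axis=axes)
    pred_sum = pred.sum(axis=axes)
    eps = spec.epsilon
    if spec.symmetric_eps:
        losses = 1.0 - (2.0 * inter + eps) / (gt_sum + pred_sum + eps)
    else:
        losses = 1.0 - 2.0 * (inter + eps) / (gt_sum + pred_sum + eps)
    if spec.reduction == "per-sample":
        return losses
    return losses.mean()
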