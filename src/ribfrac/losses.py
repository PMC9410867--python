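"""Dice + weighted binary cross-entropy segmentation objective.

Fracture voxels occupy a vanishing fraction of a chest CT patch, so a plain
voxelwise cross-entropy collapses to the background class. Two remedies are
combined additively:

* soft Dice loss ``1 - 2*sum(y*p) / (sum(y) + sum(p) + eps)`` — overlap-based,
  insensitive to the foreground/background imbalance but with an unstable
  gradient early in training;
* weighted BCE ``-mean(alpha*y*log p + (1-y)*log(1-p))`` with positive-voxel
  weight ``alpha`` (default 5) — smooth and stable everywhere.

``eps = 1e-5`` in the Dice denominator guards the all-empty patch; predictions
are clamped to [1e-7, 1 - 1e-7] before the logs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["LossValues", "dice_loss", "weighted_bce_loss", "total_loss", "total_loss_grad"]

DICE_EPS = 1e-5
CLAMP = 1e-7


@dataclasses.dataclass
class LossValues:
    dice: float
    wbce: float
    total: float
    alpha: float


def _check(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss in [0, 1]; 0 at perfect overlap, 1 at none."""
    _check(pred, target)
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    inter = float((p * y).sum())
    denom = float(y.sum() + p.sum()) + eps
    return 1.0 - 2.0 * inter / denom


def weighted_bce_loss(pred: np.ndarray, target: np.ndarray, alpha: float = 5.0) -> float:
    """Mean over voxels of -[alpha*y*log(p) + (1-y)*log(1-p)]."""
    _check(pred, target)
    p = np.clip(np.asarray(pred, dtype=np.float64), CLAMP, 1.0 - CLAMP)
    y = np.asarray(target, dtype=np.float64)
    return float(-(alpha * y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def total_loss(pred: np.ndarray, target: np.ndarray, alpha: float = 5.0) -> LossValues:
    """Sum of the Dice and weighted-BCE terms, components kept for logging."""
    d = dice_loss(pred, target)
    w = weighted_bce_loss(pred, target, alpha)
    return LossValues(dice=d, wbce=w, total=d + w, alpha=alpha)


def total_loss_grad(pred: np.ndarray, target: np.ndarray, alpha: float = 5.0) -> np.ndarray:
    """Analytic gradient of the total loss with respect to the predictions.

    The Dice term is treated per the soft formula above; the BCE gradient is
    zero where the clamp is active (matching the clamped forward value).
    """
    _check(pred, target)
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    inter = (p * y).sum()
    denom = y.sum() + p.sum() + DICE_EPS
    d_dice = (-2.0 * y * denom + 2.0 * inter) / denom**2
    pc = np.clip(p, CLAMP, 1.0 - CLAMP)
    d_wbce = -(alpha * y / pc - (1.0 - y) / (1.0 - pc)) / p.size
    d_wbce[(p < CLAMP) | (p > 1.0 - CLAMP)] = 0.0
    return (d_dice + d_wbce).astype(np.float32)
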