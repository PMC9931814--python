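"""Combo loss: weighted cross-entropy minus smoothed Dice.

L = alpha * L_mCE - (1 - alpha) * DSC, with
L_mCE = -mean(beta * t * ln p + (1 - beta) * (1 - t) * ln(1 - p)) and
DSC = (2 * sum(t * p) + smooth) / (sum t + sum p + smooth).
The Dice term is subtracted, so the loss can be negative; the optimizer
minimizes it as-is.
"""

from __future__ import annotations

import numpy as np

__all__ = ["combo_loss", "combo_loss_grad", "dice_coefficient"]


def dice_coefficient(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    return float((2.0 * (pred * target).sum() + smooth)
                 / (target.sum() + pred.sum() + smooth))


def combo_loss(
    pred: np.ndarray,
    target: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    eps: float = 1e-7,
    smooth: float = 1.0,
) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, eps, 1.0 - eps)
    mce = -np.mean(beta * target * np.log(p)
                   + (1.0 - beta) * (1.0 - target) * np.log(1.0 - p))
    return alpha * mce - (1.0 - alpha) * dice_coefficient(p, target, smooth)


def combo_loss_grad(
    pred: np.ndarray,
    target: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    eps: float = 1e-7,
    smooth: float = 1.0,
) -> np.ndarray:
    """dL/dpred, evaluated at the clipped probabilities."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    p = np.clip(pred, eps, 1.0 - eps)
    n = p.size
    dmce = -(beta * target / p - (1.0 - beta) * (1.0 - target) / (1.0 - p)) / n
    denom = target.sum() + p.sum() + smooth
    numer = 2.0 * (p * target).sum() + smooth
    ddice = (2.0 * target * denom - numer) / denom ** 2
    return alpha * dmce - (1.0 - alpha) * ddice
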