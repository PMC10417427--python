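"""Soft Tversky index and Focal Tversky loss.

The Tversky index generalizes Dice (alpha = beta = 0.5) and Jaccard
(alpha = beta = 1):

    TI = (sum p*g + s) / (sum p*g + alpha*sum p*(1-g) + beta*sum (1-p)*g + s)

with soft (probabilistic) predictions p, binary targets g and a small
smoothing constant s. The focal variant raises the complement to a power,

    L = (1 - TI) ** gamma,

which for gamma < 1 amplifies the gradient near TI -> 1, keeping pressure on
hard, small foreground regions late in training. The defaults (alpha=0.7,
beta=0.3, gamma=0.75) follow the common focal-Tversky configuration for
small-region segmentation under heavy class imbalance; all three are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TverskyConfig", "soft_tversky_index", "focal_tversky_loss",
           "focal_tversky_loss_with_grad"]


@dataclass(frozen=True)
class TverskyConfig:
    alpha: float = 0.7   # false-positive weight
    beta: float = 0.3    # false-negative weight
    gamma: float = 0.75  # focal exponent on (1 - TI)
    smooth: float = 1e-6
    # "focal_tversky": L = (1-TI)^gamma (default).
    # "focal_plus_tversky": additive combination (1-TI) + focal cross-entropy.
    mode: str = "focal_tversky"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if self.mode not in ("focal_tversky", "focal_plus_tversky"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _check(pred, target):
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def soft_tversky_index(pred_probs, target, cfg: TverskyConfig = TverskyConfig()) -> float:
    """Soft Tversky index between a probability map and a binary target."""
    p, g = _check(pred_probs, target)
    tp = float(np.sum(p * g))
    fp = float(np.sum(p * (1.0 - g)))
    fn = float(np.sum((1.0 - p) * g))
    return (tp + cfg.smooth) / (tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth)


def focal_tversky_loss(pred_probs, target, cfg: TverskyConfig = TverskyConfig()) -> float:
    """Focal Tversky loss (1 - TI)**gamma; 0 for a perfect prediction."""
    ti = soft_tversky_index(pred_probs, target, cfg)
    loss = (1.0 - ti) ** cfg.gamma
    if cfg.mode == "focal_plus_tversky":
        p, g = _check(pred_probs, target)
        pt = np.clip(np.where(g > 0.5, p, 1.0 - p), 1e-7, 1.0)
        loss = (1.0 - ti) + float(np.mean((1.0 - pt) ** 2 * -np.log(pt)))
    return loss


def focal_tversky_loss_with_grad(pred_probs, target, cfg: TverskyConfig = TverskyConfig()):
    """Loss and its gradient with respect to the foreground probabilities.

    Used by the training engine; the gradient of (1-TI)^gamma is clipped at
    1 - TI >= 1e-12 to stay finite for gamma < 1 near a perfect prediction.
    """
    p, g = _check(pred_probs, target)
    tp = float(np.sum(p * g))
    fp = float(np.sum(p * (1.0 - g)))
    fn = float(np.sum((1.0 - p) * g))
    num = tp + cfg.smooth
    den = tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth
    ti = num / den
    one_minus = max(1.0 - ti, 1e-12)
    loss = one_minus ** cfg.gamma
    # dTI/dp_i = (g_i * den - num * dden/dp_i) / den^2
    dden = g + cfg.alpha * (1.0 - g) - cfg.beta * g
    dti = (g * den - num * dden) / (den * den)
    dloss = -cfg.gamma * one_minus ** (cfg.gamma - 1.0) * dti
    return loss, dloss
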