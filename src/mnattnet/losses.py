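"""Binary cross-entropy and focal loss on positive-class probabilities.

Focal loss, L(p, y) = -y (1-p)^gamma log p - (1-y) p^gamma log(1-p),
down-weights well-classified samples; gamma = 0 recovers cross-entropy
exactly and gamma = 2 is the default used for training. There is no alpha
class-balancing term: class imbalance is handled upstream by augmentation
and negative downsampling in the dataset pipeline.

Probabilities are clamped to [EPS, 1-EPS] (EPS = 1e-7) inside the
logarithms; batch reduction is the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FocalParams", "cross_entropy", "focal_loss", "focal_dlogits", "EPS"]

EPS = 1e-7


@dataclass
class FocalParams:
    """Focusing parameter gamma >= 0; gamma=0 is plain cross-entropy."""

    gamma: float = 2.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(p, EPS, 1 - EPS)


def cross_entropy(p, y, reduce: bool = True):
    """-[y log p + (1-y) log(1-p)] per sample; mean over the batch."""
    p = _check_p(p)
    y = np.asarray(y, dtype=np.float64)
    loss = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    return float(loss.mean()) if reduce else loss


def focal_loss(p, y, params: FocalParams | float = FocalParams(), reduce: bool = True):
    """-y (1-p)^g log p - (1-y) p^g log(1-p) per sample; mean over the batch."""
    g = params.gamma if isinstance(params, FocalParams) else float(params)
    if g < 0:
        raise ValueError(f"gamma must be >= 0, got {g}")
    p = _check_p(p)
    y = np.asarray(y, dtype=np.float64)
    loss = -(y * (1 - p) ** g * np.log(p) + (1 - y) * p ** g * np.log1p(-p))
    return float(loss.mean()) if reduce else loss


def focal_dlogits(probs: np.ndarray, y: np.ndarray, gamma: float = 2.0) -> np.ndarray:
    """Mean-reduced focal-loss gradient w.r.t. the two class logits.

    With p the positive-class softmax probability of a 2-way head,
    dp/dz1 = p(1-p) = -dp/dz0, and the 1/p (resp. 1/(1-p)) singularities of
    dL/dp cancel against it, giving the closed forms

        y = 1:  dL/dz1 = gamma * p * (1-p)^gamma * log p - (1-p)^(gamma+1)
        y = 0:  dL/dz1 = p^(gamma+1) - gamma * (1-p) * p^gamma * log(1-p)

    which are singularity-free. gamma = 0 reduces to the usual p - y.
    Returns an (N, 2) array already divided by the batch size.
    """
    p = np.clip(np.asarray(probs[:, 1], dtype=np.float64), EPS, 1 - EPS)
    y = np.asarray(y, dtype=np.float64)
    q = 1 - p
    dz1_pos = gamma * p * q ** gamma * np.log(p) - q ** (gamma + 1)
    dz1_neg = p ** (gamma + 1) - gamma * q * p ** gamma * np.log1p(-p)
    dz1 = np.where(y == 1, dz1_pos, dz1_neg) / len(p)
    out = np.empty((len(p), 2), dtype=np.float32)
    out[:, 1] = dz1
    out[:, 0] = -dz1
    return out
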