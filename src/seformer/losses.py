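"""Composite segmentation loss: L = alpha * BCE + (1 - alpha) * soft Dice.

BCE optimizes pixel-wise accuracy; the soft Dice term optimizes region
overlap directly and is what keeps training stable under the severe
foreground/background imbalance of vessel masks (vessels occupy roughly
5-12% of the field of view).  Both terms consume *probabilities* in (0,1);
the caller applies the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.tensor import Tensor, as_tensor


@dataclass(frozen=True)
class LossConfig:
    """Mixing weight and numerical floors for the composite loss.

    alpha:     BCE weight in [0,1]; the Dice term gets (1 - alpha).
    eps_bce:   probability clamp, p in [eps, 1-eps], keeps log finite.
    eps_dice:  smoothing added to the Dice numerator and denominator.
    """

    alpha: float = 0.5
    eps_bce: float = 1e-7
    eps_dice: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0,1], got {self.alpha}")
        if self.eps_bce <= 0 or self.eps_dice <= 0:
            raise ValueError("loss epsilons must be positive")


def _check_shapes(prob: Tensor, target: Tensor):
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")


def bce_loss(prob, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    prob, target = as_tensor(prob), as_tensor(target)
    _check_shapes(prob, target)
    p = prob.clip(eps, 1.0 - eps)
    t = Tensor(target.data.astype(p.dtype))
    ll = t * p.log() + (1.0 - t) * (1.0 - p).log()
    return -ll.mean()


def soft_dice_loss(prob, target, eps: float = 1e-6) -> Tensor:
    """1 - soft Dice, computed per image and averaged over the batch.

    Inputs of rank >= 2 are treated as (batch, ...); rank-1 inputs as a
    single image.
    """
    prob, target = as_tensor(prob), as_tensor(target)
    _check_shapes(prob, target)
    b = prob.shape[0] if prob.ndim >= 2 else 1
    p = prob.reshape(b, -1) if prob.ndim >= 2 else prob.reshape(1, -1)
    t = Tensor(target.data.astype(p.dtype)).reshape(p.shape)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    dice = (2.0 * inter + eps) / (denom + eps)
    return (1.0 - dice).mean()


def combined_loss(prob, target, cfg: LossConfig = LossConfig()) -> Tensor:
    """alpha * BCE + (1 - alpha) * Dice."""
    a = cfg.alpha
    if a == 1.0:
        return bce_loss(prob, target, cfg.eps_bce)
    if a == 0.0:
        return soft_dice_loss(prob, target, cfg.eps_dice)
    return (a * bce_loss(prob, target, cfg.eps_bce)
            + (1.0 - a) * soft_dice_loss(prob, target, cfg.eps_dice))
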