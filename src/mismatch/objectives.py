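"""Losses: soft Dice, batch-normalised consistency, and their combination.

Supervised signal is a soft Dice loss between each decoder's probability
map and the binary mask, averaged over the two decoders.  Unsupervised
signal is a mean-squared-error consistency term between the two decoders'
predictions, optionally standardised along the batch dimension first, and
weighted by ``alpha`` (default 0.002).  Two training regimes are supported:

* ``streaming`` — a step is either labelled (Dice only) or unlabelled
  (``alpha`` x consistency only); labelled slices are interleaved sparsely
  so they are not revisited within an epoch;
* ``combined`` — each step draws a labelled and an unlabelled batch and
  sums both terms.

With ``stop_gradient`` on, the consistency term treats each decoder's
prediction as a constant target for the other (symmetric stop-gradient);
the loss value is unchanged but each decoder only receives the gradient of
its own branch.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import Tensor, as_tensor
from .network import PairedPrediction

__all__ = ["LossConfig", "dice_loss", "normalise_batchwise",
           "consistency_loss", "total_loss"]


@dataclass(frozen=True)
class LossConfig:
    """Loss hyper-parameters.

    alpha
        Consistency weight (dimensionless, >= 0). 0.002 in the streaming
        reference setting; 1.0 in the combined 3-D setting.
    normalise_batch
        Standardise the paired predictions per channel over the whole batch
        before the squared error.
    stop_gradient
        Symmetric stop-gradient on the consistency targets.
    dice_smooth
        Additive smoothing of the Dice ratio for empty masks.
    """

    alpha: float = 0.002
    normalise_batch: bool = True
    stop_gradient: bool = True
    dice_smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")


def _check_shapes(a, b) -> None:
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"shape mismatch: {tuple(a.shape)} vs {tuple(b.shape)}")


def dice_loss(p, y, smooth: float = 1e-6) -> Tensor:
    """``1 - (2*sum(p*y)+s) / (sum(p)+sum(y)+s)`` over all pixels."""
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    inter = (p * y.detach()).sum()
    denom = p.sum() + y.detach().sum()
    return 1.0 - (inter * 2.0 + smooth) / (denom + smooth)


def normalise_batchwise(p, eps: float = 1e-12) -> Tensor:
    """Standardise a (N, C, *S) batch per channel over all pixels.

    Uses population statistics across the whole batch; a constant batch maps
    to all zeros through the guarded denominator.
    """
    p = as_tensor(p)
    axes = (0,) + tuple(range(2, p.ndim))
    mu = p.mean(axis=axes, keepdims=True)
    centred = p - mu
    var = (centred * centred).mean(axis=axes, keepdims=True)
    return centred * ((var + eps) ** -0.5)


def consistency_loss(p1, p2, cfg: LossConfig = LossConfig()) -> Tensor:
    """Mean squared disagreement between the decoders' predictions."""
    p1, p2 = as_tensor(p1), as_tensor(p2)
    _check_shapes(p1, p2)
    q1 = normalise_batchwise(p1) if cfg.normalise_batch else p1
    q2 = normalise_batchwise(p2) if cfg.normalise_batch else p2
    if cfg.stop_gradient:
        d1 = q1 - q2.detach()
        d2 = q1.detach() - q2
        return ((d1 * d1).mean() + (d2 * d2).mean()) * 0.5
    d = q1 - q2
    return (d * d).mean()


def total_loss(pred: PairedPrediction, mask=None, *, labelled: bool,
               regime: str = "streaming", cfg: LossConfig = LossConfig(),
               unlabelled_pred: PairedPrediction | None = None
               ) -> tuple[Tensor, dict]:
    """Step loss for one batch, plus a component breakdown.

    Streaming regime: labelled steps return the mean Dice loss of the two
    decoders, unlabelled steps return ``alpha * consistency``.  Combined
    regime: Dice on the labelled batch plus ``alpha`` x consistency in one
    step; the consistency term is computed on ``unlabelled_pred`` when
    given, otherwise on the labelled batch's own paired predictions.
    """
    if regime not in ("streaming", "combined"):
        raise ValueError(f"unknown regime {regime!r}")
    parts: dict[str, float] = {"regime": regime}
    if labelled:
        if mask is None:
            raise ValueError("labelled step requires a mask")
        d1 = dice_loss(pred.p1, mask, smooth=cfg.dice_smooth)
        d2 = dice_loss(pred.p2, mask, smooth=cfg.dice_smooth)
        loss = (d1 + d2) * 0.5
        parts["dice1"], parts["dice2"] = d1.item(), d2.item()
        if regime == "combined":
            target = unlabelled_pred if unlabelled_pred is not None else pred
            cons = consistency_loss(target.p1, target.p2, cfg)
            loss = loss + cons * cfg.alpha
            parts["consistency"] = cons.item()
    else:
        cons = consistency_loss(pred.p1, pred.p2, cfg)
        loss = cons * cfg.alpha
        parts["consistency"] = cons.item()
    parts["total"] = loss.item()
    return loss, parts
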