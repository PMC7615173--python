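"""Semi-supervised training loop, checkpoint averaging and evaluation.

Two semi-supervised regimes mirror the two reference settings:

* ``streaming`` — each epoch walks the shuffled unlabelled stream once and
  interleaves the labelled slices sparsely at rate ``L/U`` so every
  labelled item is visited exactly once per pass; a labelled step minimises
  Dice only, an unlabelled step minimises ``alpha`` x consistency only
  (defaults: lr 2e-5, batch 1).
* ``combined`` — each step draws one labelled and one unlabelled batch and
  minimises Dice + ``alpha`` x consistency jointly (defaults: lr 1e-2,
  batch 4).

A ``supervised`` regime (labelled items only) trains the baselines.  When
``alpha == 0`` an unlabelled streaming step contributes no gradient, so it
is skipped outright; the resulting parameter trajectory is bit-identical to
the supervised regime under a shared seed, which the tests assert.

After the last epoch the returned model is the arithmetic mean of the
parameters saved at the ends of the last ``avg_last_k`` epochs; a
prediction-ensemble alternative over the same checkpoints is available via
:func:`predict_ensemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import bin_pixels, segmentation_metrics
from .nn import Adam, Module, Tensor
from .objectives import LossConfig, total_loss

__all__ = ["TrainConfig", "DataStream", "TrainResult", "train",
           "average_checkpoints", "predict", "predict_ensemble",
           "evaluate_dataset"]

_REGIMES = ("streaming", "combined", "supervised")
_DEFAULT_LR = {"streaming": 2e-5, "combined": 1e-2, "supervised": 2e-5}
_DEFAULT_BATCH = {"streaming": 1, "combined": 4, "supervised": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, library-default betas).

    ``lr`` and ``batch_size`` default per regime: 2e-5 / batch 1 for
    streaming and supervised, 1e-2 / batch 4 for combined.
    """

    regime: str = "streaming"
    epochs: int = 50
    lr: float | None = None
    batch_size: int | None = None
    avg_last_k: int | None = None  # default: min(10, epochs)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.avg_last_k is not None and not 1 <= self.avg_last_k <= self.epochs:
            raise ValueError("avg_last_k must be in [1, epochs]")
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be positive")

    @property
    def effective_avg_last_k(self) -> int:
        return self.avg_last_k if self.avg_last_k is not None else min(10, self.epochs)

    @property
    def effective_lr(self) -> float:
        return self.lr if self.lr is not None else _DEFAULT_LR[self.regime]

    @property
    def effective_batch(self) -> int:
        return self.batch_size if self.batch_size is not None else _DEFAULT_BATCH[self.regime]


@dataclass
class DataStream:
    """Labelled/unlabelled/validation/test splits.

    Labelled entries are ``(image, mask)`` pairs with image shaped
    ``(channels, *spatial)`` and mask ``(*spatial,)``; unlabelled entries
    are images only.
    """

    labelled: list = field(default_factory=list)
    unlabelled: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)


@dataclass
class TrainResult:
    network: Module
    history: pd.DataFrame
    checkpoints: list[dict[str, np.ndarray]]
    val_iou: float


def _as_batch(images) -> Tensor:
    return Tensor(np.stack([np.asarray(im, dtype=float) for im in images]))


def _mask_batch(masks) -> np.ndarray:
    return np.stack([np.asarray(m, dtype=float) for m in masks])[:, None]


def _streaming_schedule(n_lab: int, n_unlab: int,
                        rng_l: np.random.Generator,
                        rng_u: np.random.Generator) -> list[tuple[str, int]]:
    """One epoch of events: unlabelled pass with labelled items interleaved
    at evenly spaced positions, each labelled item exactly once."""
    order_u = rng_u.permutation(n_unlab)
    order_l = rng_l.permutation(n_lab)
    events: list[tuple[str, int]] = [("u", int(i)) for i in order_u]
    total = n_lab + n_unlab
    for j, idx in enumerate(order_l):
        events.insert(min(j * total // max(n_lab, 1), len(events)), ("l", int(idx)))
    return events


def _step(network, optimiser, loss) -> None:
    network.zero_grad()
    loss.backward()
    optimiser.step()


def train(network: Module, data: DataStream, cfg: TrainConfig = TrainConfig(),
          loss_cfg: LossConfig = LossConfig()) -> TrainResult:
    """Train ``network`` on ``data`` and return the checkpoint-averaged model."""
    if not data.labelled:
        raise ValueError("labelled set must be nonempty")
    if cfg.regime != "supervised" and not data.unlabelled:
        raise ValueError(f"{cfg.regime} regime requires unlabelled data")
    optimiser = Adam(network.parameters(), lr=cfg.effective_lr)
    records: list[dict] = []
    checkpoints: list[dict[str, np.ndarray]] = []
    step_counter = 0

    for epoch in range(cfg.epochs):
        rng_l = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, epoch, 0)))
        rng_u = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, epoch, 1)))
        if cfg.regime in ("streaming", "supervised"):
            if cfg.regime == "supervised":
                events = [("l", int(i)) for i in rng_l.permutation(len(data.labelled))]
            else:
                events = _streaming_schedule(len(data.labelled), len(data.unlabelled),
                                             rng_l, rng_u)
            for kind, idx in events:
                if kind == "u" and loss_cfg.alpha == 0.0:
                    continue  # inert consistency term: no forward, no update
                if kind == "l":
                    image, mask = data.labelled[idx]
                    pred = network(_as_batch([image]))
                    loss, parts = total_loss(pred, _mask_batch([mask]),
                                             labelled=True, regime="streaming",
                                             cfg=loss_cfg)
                else:
                    pred = network(_as_batch([data.unlabelled[idx]]))
                    loss, parts = total_loss(pred, labelled=False,
                                             regime="streaming", cfg=loss_cfg)
                _check_finite(parts, epoch, step_counter)
                _step(network, optimiser, loss)
                records.append({"epoch": epoch, "step": step_counter,
                                "labelled": kind == "l", **parts})
                step_counter += 1
        else:  # combined
            batch = cfg.effective_batch
            order_l = rng_l.permutation(len(data.labelled))
            order_u = rng_u.permutation(len(data.unlabelled))
            n_steps = max(1, int(np.ceil(len(order_u) / batch)))
            for s in range(n_steps):
                li = [int(order_l[(s * batch + j) % len(order_l)]) for j in range(batch)]
                ui = [int(order_u[(s * batch + j) % len(order_u)]) for j in range(batch)]
                images, masks = zip(*[data.labelled[i] for i in li])
                pred_l = network(_as_batch(images))
                pred_u = network(_as_batch([data.unlabelled[i] for i in ui]))
                loss, parts = total_loss(pred_l, _mask_batch(masks), labelled=True,
                                         regime="combined", cfg=loss_cfg,
                                         unlabelled_pred=pred_u)
                _check_finite(parts, epoch, step_counter)
                _step(network, optimiser, loss)
                records.append({"epoch": epoch, "step": step_counter,
                                "labelled": True, **parts})
                step_counter += 1
        checkpoints.append(network.state_dict())
        if len(checkpoints) > cfg.effective_avg_last_k:
            checkpoints.pop(0)

    network.load_state_dict(average_checkpoints(checkpoints))
    val_iou = float("nan")
    if data.val:
        val_iou = float(evaluate_dataset(network, data.val)["iou"].mean())
    history = pd.DataFrame.from_records(records)
    return TrainResult(network=network, history=history,
                       checkpoints=checkpoints, val_iou=val_iou)


def _check_finite(parts: dict, epoch: int, step: int) -> None:
    if not np.isfinite(parts["total"]):
        raise ArithmeticError(
            f"non-finite loss {parts['total']} at epoch {epoch}, step {step}; "
            f"components: { {k: v for k, v in parts.items() if k != 'regime'} }")


def average_checkpoints(checkpoints: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Arithmetic mean of parameter sets sharing one architecture."""
    if not checkpoints:
        raise ValueError("no checkpoints to average")
    keys = set(checkpoints[0])
    for ck in checkpoints[1:]:
        if set(ck) != keys:
            raise ValueError("checkpoints have mismatched parameter names")
        for k in keys:
            if ck[k].shape != checkpoints[0][k].shape:
                raise ValueError(f"checkpoints have mismatched shapes for {k}")
    return {k: np.mean([ck[k] for ck in checkpoints], axis=0) for k in keys}


def predict(network: Module, image: np.ndarray) -> np.ndarray:
    """Fused foreground probability map for one ``(channels, *spatial)`` image."""
    return network(_as_batch([image])).fused.data[0, 0]


def predict_ensemble(network: Module, checkpoints: list[dict[str, np.ndarray]],
                     image: np.ndarray) -> np.ndarray:
    """Average the *predictions* of several checkpoints (alternative to
    parameter averaging); restores the network's parameters afterwards."""
    saved = network.state_dict()
    try:
        preds = []
        for ck in checkpoints:
            network.load_state_dict(ck)
            preds.append(predict(network, image))
    finally:
        network.load_state_dict(saved)
    return np.mean(preds, axis=0)


def evaluate_dataset(network: Module, pairs, threshold: float = 0.5,
                     bins: int = 5) -> pd.DataFrame:
    """Per-image IoU/Dice/ECE of the fused prediction on labelled pairs."""
    rows = []
    for image, mask in pairs:
        prob = predict(network, image)
        seg = segmentation_metrics(prob >= threshold, mask)
        rows.append({"iou": seg["iou"], "dice": seg["dice"],
                     "ece": bin_pixels(prob, mask, M=bins).ece})
    return pd.DataFrame(rows)
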