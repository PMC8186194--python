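"""Training loop for the segmentation network (cross-entropy + soft Dice, Adam)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ctrkit.segmentation.model import CLASS_HEART, CLASS_LUNG, UNet, predict
from ctrkit.segmentation.nn import ce_dice_loss


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 8
    dice_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


def _stack(cases) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([np.asarray(c.image, dtype=np.float64) for c in cases])[:, None]
    labels = np.stack([c.class_map() for c in cases])
    return images, labels


def train(model: UNet, cases: Sequence, config: TrainConfig | None = None) -> list[float]:
    """Train in place on labelled phantoms; returns per-epoch mean losses.

    ``config.epochs == 0`` is a no-op (the model is left untouched).
    Deterministic for a fixed seed on a single thread.
    """
    if not cases:
        raise ValueError("need at least one labelled case")
    config = config or TrainConfig()
    images, labels = _stack(cases)
    n = images.shape[0]
    rng = np.random.default_rng(config.seed)
    optimizer = model.make_optimizer(config.learning_rate)

    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(images[idx])
            loss, dlogits = ce_dice_loss(logits, labels[idx], config.dice_weight)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.zero_grads()
            model.backward(dlogits)
            optimizer.step(model.grads())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def evaluate_dice(model: UNet, cases: Sequence) -> dict[str, float]:
    """Mean lung and heart Dice of predictions against the class-map labels.

    Lung truth excludes heart-covered pixels, matching the training labels.
    """
    lung_scores, heart_scores = [], []
    for case in cases:
        out = predict(model, case.image)
        labels = case.class_map()
        lung_scores.append(dice_coefficient(out.lung_mask, labels == CLASS_LUNG))
        heart_scores.append(dice_coefficient(out.heart_mask, labels == CLASS_HEART))
    return {
        "lung_dice": float(np.mean(lung_scores)),
        "heart_dice": float(np.mean(heart_scores)),
    }
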