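"""Training loop, loss, thresholding and end-to-end evaluation.

Training runs a fixed number of optimiser steps per epoch over shuffled
whole-image batches (no patch extraction). The loss is per-pixel binary
cross-entropy by default, optionally combined with a soft-Dice term for
class imbalance; the optimiser is Adam. Everything is deterministic
given the seed on single-threaded CPU execution: the data order, the
weight initialisation and the arithmetic contain no other randomness.

Evaluation reflect-pads each test image to the next multiple of
2**depth (needed e.g. for 565x584 or 304x304 inputs at depth 4),
predicts, crops the padding back off so border pixels never enter the
counts, binarises at the configured threshold and scores with the
confusion-count statistics.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import metrics as metrics_mod
from . import nn
from .model import ModelConfig, VesselSegModel, build_model, save_checkpoint
from .synthetic import ImageSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "binarize",
    "pad_to_divisible",
    "train",
    "evaluate",
    "EvaluationResult",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    steps_per_epoch: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "bce"  # or "bce_plus_dice"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 1:
            raise ValueError("epochs, steps_per_epoch and batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("bce", "bce_plus_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    checkpoint_path: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "loss": self.loss,
            "accuracy": self.accuracy,
            "epoch_seconds": self.epoch_seconds,
            "checkpoint_path": self.checkpoint_path,
        }


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; pixels >= threshold become vessel."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (prob_map >= threshold).astype(np.uint8)


def pad_to_divisible(arr: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad trailing rows/cols so H and W divide ``divisor``.

    Returns the padded array and the original (H, W) for cropping back.
    """
    h, w = arr.shape[:2]
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph == 0 and pw == 0:
        return arr, (h, w)
    pad = ((0, ph), (0, pw)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, pad, mode="reflect"), (h, w)


def _as_batch(samples: Sequence[ImageSample], idx: np.ndarray, in_channels: int) -> tuple[np.ndarray, np.ndarray]:
    imgs, masks = [], []
    for i in idx:
        s = samples[int(i)]
        img = s.image
        if in_channels == 1 and img.ndim == 3:
            raise ValueError(f"sample {s.sample_id} is RGB but the model expects grayscale input")
        imgs.append(img[None] if img.ndim == 2 else img.transpose(2, 0, 1))
        masks.append(s.mask[None])
    return np.stack(imgs), np.stack(masks).astype(np.float64)


def train(
    model_config: ModelConfig,
    samples: Sequence[ImageSample],
    train_config: TrainConfig,
    out_dir: Optional[str | Path] = None,
    log_every: int = 0,
) -> tuple[VesselSegModel, TrainHistory]:
    """Train a freshly initialised model on in-memory samples.

    Runs ``epochs * steps_per_epoch`` Adam steps over seeded shuffled
    batches, tracking mean loss and per-pixel training accuracy per
    epoch. The weights with the best epoch loss are kept and, when
    ``out_dir`` is given, written as ``checkpoint.npz`` (+ JSON config
    sidecar) alongside a JSON history.
    """
    if not samples:
        raise ValueError("training sample list is empty")
    for s in samples:
        d = model_config.divisor
        if s.shape[0] % d or s.shape[1] % d:
            raise ValueError(
                f"sample {s.sample_id} has shape {s.shape}, not divisible by 2**depth = {d}; "
                "pad or crop training images upstream"
            )
    rng = np.random.default_rng(train_config.seed)
    model = build_model(model_config, seed=int(rng.integers(2**31)))
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    history = TrainHistory()
    n = len(samples)
    order = rng.permutation(n)
    cursor = 0
    best_loss = np.inf
    best_state: Optional[dict[str, np.ndarray]] = None
    model.train(True)
    for epoch in range(train_config.epochs):
        t0 = time.perf_counter()
        losses, accs = [], []
        for step in range(train_config.steps_per_epoch):
            idx = []
            for _ in range(train_config.batch_size):
                if cursor == n:
                    order = rng.permutation(n)
                    cursor = 0
                idx.append(order[cursor])
                cursor += 1
            x, y = _as_batch(samples, np.array(idx), model_config.in_channels)
            logits = model.forward_logits(x)
            loss_t = nn.bce_with_logits(logits, y)
            if train_config.loss == "bce_plus_dice":
                loss_t = nn.scalar_add(loss_t, nn.soft_dice_loss(nn.sigmoid(logits), y))
            loss = float(loss_t.data)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch + 1}, step {step + 1}"
                )
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            losses.append(loss)
            accs.append(float(((logits.data >= 0.0) == (y >= 0.5)).mean()))
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(float(np.mean(accs)))
        history.epoch_seconds.append(time.perf_counter() - t0)
        if history.loss[-1] < best_loss:
            best_loss = history.loss[-1]
            best_state = model.state_dict()
        if log_every and (epoch + 1) % log_every == 0:
            print(
                f"epoch {epoch + 1}/{train_config.epochs}: "
                f"loss={history.loss[-1]:.4f} acc={history.accuracy[-1]:.4f}"
            )
    if best_state is not None:
        model.load_state_dict(best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "checkpoint.npz"
        save_checkpoint(model, ckpt)
        history.checkpoint_path = str(ckpt)
        (out_dir / "history.json").write_text(json.dumps(history.as_dict(), indent=2))
    return model, history


@dataclass
class EvaluationResult:
    aggregate: metrics_mod.MetricsReport
    per_image: list[dict]
    mode: str

    def as_dict(self, percent: bool = True) -> dict:
        return {
            "aggregation": self.mode,
            "aggregate": self.aggregate.as_dict(percent=percent),
            "per_image": self.per_image,
        }


def evaluate(
    model: VesselSegModel,
    samples: Sequence[ImageSample],
    threshold: float = 0.5,
    aggregation: str = "micro",
    restrict_roi: bool = True,
) -> EvaluationResult:
    """Predict every sample, binarise, and score.

    Metrics are restricted to the field-of-view ROI when a sample
    carries one and ``restrict_roi`` is True.
    """
    if not samples:
        raise ValueError("evaluation sample list is empty")
    counts_list, rows = [], []
    for s in samples:
        prob = model.predict(s.image)
        pred = binarize(prob, threshold)
        roi = s.roi if restrict_roi else None
        c = metrics_mod.confusion_counts(pred, s.mask, roi)
        counts_list.append(c)
        report = metrics_mod.compute_metrics(c)
        rows.append(
            {
                "sample_id": s.sample_id,
                "TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn,
                **report.as_dict(percent=False),
            }
        )
    agg = metrics_mod.aggregate(counts_list, mode=aggregation)
    return EvaluationResult(aggregate=agg, per_image=rows, mode=aggregation)
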