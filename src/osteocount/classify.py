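"""Osteoclast / non-osteoclast crop classification.

A residual CNN student is trained with Adam on cross-entropy plus L2; an
evaluation ("teacher") copy of the weights is maintained as an exponential
moving average of the student after every optimizer step (the mean-teacher
scheme), and the teacher snapshot with the best validation accuracy is the
returned classifier. Crops are z-score normalized per channel with statistics
frozen from the training split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .augment import AugmentationSpec, apply_augmentation
from .errors import ValidationError
from .segmentation import CellCrop

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1

LABEL_NAMES = {0: "non_osteoclast", 1: "osteoclast"}


@dataclasses.dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/SD over the pooled pixels of the training crops."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    eps: float = 1e-6


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the classifier training run.

    The published full-scale profile is ResNet-18 with learning rate 0.002,
    L2 1e-5, batch 256, 500 epochs and EMA smoothing 0.999; the default here
    is the desk-scale profile (small net, 20 epochs, batch 64) with the same
    optimizer settings.
    """

    learning_rate: float = 0.002
    l2: float = 1e-5
    batch_size: int = 64
    epochs: int = 20
    ema_alpha: float = 0.999
    seed: int = 0
    arch: str = "small"
    augment: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ema_alpha <= 1.0:
            raise ValidationError("ema_alpha must be in [0, 1]")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValidationError("learning rate, batch size and epochs must be positive")

    @classmethod
    def paper_scale(cls, **overrides) -> "TrainingConfig":
        base = dict(learning_rate=0.002, l2=1e-5, batch_size=256, epochs=500,
                    ema_alpha=0.999, arch="resnet18")
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class TeacherState:
    """EMA parameter set tracking a student model."""

    params: dict[str, np.ndarray]
    buffers: dict[str, np.ndarray]
    alpha: float


@dataclasses.dataclass(frozen=True)
class Prediction:
    p_non_oc: float
    p_oc: float
    label: int  # 0 non-osteoclast, 1 osteoclast

    @property
    def label_name(self) -> str:
        return LABEL_NAMES[self.label]


@dataclasses.dataclass
class TrainedClassifier:
    """A trained teacher model plus the frozen training statistics."""

    model: nn.Model
    stats: ChannelStats
    config: TrainingConfig


def _crop_array(crops: Sequence[CellCrop] | np.ndarray) -> np.ndarray:
    if isinstance(crops, np.ndarray):
        arr = crops
    else:
        arr = np.stack([c.pixels for c in crops])
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValidationError(f"expected N x H x W x 3 crops, got {arr.shape}")
    return arr


def compute_channel_stats(crops: Sequence[CellCrop] | np.ndarray,
                          eps: float = 1e-6) -> ChannelStats:
    """Per-channel mean and SD over all pixels of the training crops."""
    arr = _crop_array(crops)
    if arr.shape[0] == 0:
        raise ValidationError("cannot compute channel statistics of an empty crop set")
    flat = arr.reshape(-1, 3).astype(np.float64)
    return ChannelStats(
        mean=tuple(float(m) for m in flat.mean(axis=0)),
        std=tuple(float(s) for s in flat.std(axis=0)),
        eps=eps,
    )


def normalize_crop(crop: np.ndarray | CellCrop, stats: ChannelStats) -> np.ndarray:
    """Z-score a crop per channel: (x - mu) / max(sigma, eps)."""
    pixels = crop.pixels if isinstance(crop, CellCrop) else np.asarray(crop)
    mu = np.asarray(stats.mean, dtype=np.float64)
    sigma = np.maximum(np.asarray(stats.std, dtype=np.float64), stats.eps)
    return (pixels.astype(np.float64) - mu) / sigma


def _normalize_batch(arr: np.ndarray, stats: ChannelStats,
                     dtype=np.float32) -> np.ndarray:
    mu = np.asarray(stats.mean)
    sigma = np.maximum(np.asarray(stats.std), stats.eps)
    out = (arr.astype(np.float64) - mu) / sigma
    # NCHW layout for the network
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)).astype(dtype)


def ema_update(teacher: TeacherState, student_params: dict[str, np.ndarray],
               student_buffers: dict[str, np.ndarray] | None = None,
               alpha: float | None = None) -> TeacherState:
    """theta_t = alpha * theta_{t-1} + (1 - alpha) * theta'_t, in place."""
    alpha = teacher.alpha if alpha is None else alpha
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    for key, theta in teacher.params.items():
        if theta.shape != student_params[key].shape:
            raise ValidationError(f"shape mismatch for {key!r}")
        theta *= alpha
        theta += (1.0 - alpha) * student_params[key]
    if student_buffers:
        for key, buf in teacher.buffers.items():
            buf *= alpha
            buf += (1.0 - alpha) * student_buffers[key]
    return teacher


def _accuracy(model: nn.Model, x: np.ndarray, labels: np.ndarray,
              batch_size: int = 256) -> float:
    correct = 0
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start : start + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == labels[start : start + batch_size]).sum())
    return correct / x.shape[0]


def train_classifier(
    train_crops: Sequence[CellCrop] | np.ndarray,
    train_labels: np.ndarray,
    val_crops: Sequence[CellCrop] | np.ndarray,
    val_labels: np.ndarray,
    config: TrainingConfig | None = None,
    augmentation: AugmentationSpec | None = None,
) -> tuple[TrainedClassifier, dict]:
    """Train the student with Adam and return the best-validation teacher.

    Per step: augment the batch, normalize, student forward/backward on
    cross-entropy + L2, Adam update, then EMA update of the teacher. Per
    epoch the teacher's validation accuracy is recorded, and the snapshot
    with the maximum accuracy (earliest epoch on ties) is returned.
    """
    config = config or TrainingConfig()
    train_arr = _crop_array(train_crops)
    val_arr = _crop_array(val_crops)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    val_labels = np.asarray(val_labels, dtype=np.int64)
    if len(np.unique(train_labels)) < 2:
        raise ValidationError("training set contains a single class")
    n = train_arr.shape[0]
    batch_size = config.batch_size
    if batch_size > n:
        warnings.warn(f"batch size {batch_size} exceeds dataset size {n}; clamping")
        batch_size = n

    stats = compute_channel_stats(train_arr)
    val_x = _normalize_batch(val_arr, stats)

    rng = np.random.default_rng(config.seed)
    student = nn.build_model(config.arch, seed=config.seed)
    teacher_model = nn.build_model(config.arch, seed=config.seed)
    teacher = TeacherState(*teacher_model.state_copy(), alpha=config.ema_alpha)
    optimizer = nn.Adam(student.parameters(), lr=config.learning_rate,
                        weight_decay=config.l2)
    spec = augmentation or AugmentationSpec()

    history: dict = {"val_accuracy": [], "train_loss": []}
    best = {"acc": -1.0, "epoch": -1, "params": None, "buffers": None}
    global_step = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_steps = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = train_arr[idx]
            if config.augment:
                batch = np.stack(
                    [apply_augmentation(img, spec, rng) for img in batch]
                )
            x = _normalize_batch(batch, stats)
            logits = student.forward(x, train=True)
            loss, dlogits = nn.cross_entropy(logits, train_labels[idx])
            student.backward(dlogits)
            optimizer.step(student.gradients())
            # mean-teacher convention: ramp the smoothing up from 0 so the
            # teacher is an unbiased running average early in training
            alpha_t = min(config.ema_alpha, 1.0 - 1.0 / (global_step + 1))
            ema_update(teacher, student.parameters(), student.buffers(), alpha=alpha_t)
            global_step += 1
            epoch_loss += loss
            n_steps += 1
        teacher_model.load_state(teacher.params, teacher.buffers)
        val_acc = _accuracy(teacher_model, val_x, val_labels)
        history["val_accuracy"].append(val_acc)
        history["train_loss"].append(epoch_loss / max(n_steps, 1))
        if val_acc > best["acc"]:
            best = {
                "acc": val_acc,
                "epoch": epoch,
                "params": {k: v.copy() for k, v in teacher.params.items()},
                "buffers": {k: v.copy() for k, v in teacher.buffers.items()},
            }
        logger.info("epoch %d: teacher val accuracy %.4f", epoch, val_acc)

    history["selected_epoch"] = best["epoch"]
    history["best_val_accuracy"] = best["acc"]
    history["final_student"] = student.state_copy()
    teacher_model.load_state(best["params"], best["buffers"])
    return TrainedClassifier(model=teacher_model, stats=stats, config=config), history


def predict_crops(
    crops: Sequence[CellCrop] | np.ndarray,
    classifier: TrainedClassifier,
    batch_size: int = 256,
) -> list[Prediction]:
    """Classify crops with the teacher; batch order is preserved."""
    arr = _crop_array(crops)
    if arr.shape[0] == 0:
        return []
    x = _normalize_batch(arr, classifier.stats)
    preds: list[Prediction] = []
    for start in range(0, x.shape[0], batch_size):
        logits = classifier.model.forward(x[start : start + batch_size], train=False)
        probs = nn.softmax(logits.astype(np.float64))
        for row in probs:
            preds.append(
                Prediction(
                    p_non_oc=float(row[0]),
                    p_oc=float(row[1]),
                    label=int(row.argmax()),
                )
            )
    return preds


# ---------------------------------------------------------------------------
# Checkpoint round-trip

def config_hash(config: TrainingConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(classifier: TrainedClassifier, path: str | Path) -> None:
    """Single-archive checkpoint: tensors + stats + arch tag + config hash."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "arch": classifier.model.arch,
        "stats": dataclasses.asdict(classifier.stats),
        "config": dataclasses.asdict(classifier.config),
        "config_hash": config_hash(classifier.config),
    }
    arrays = {f"param:{k}": v for k, v in classifier.model.parameters().items()}
    arrays.update({f"buffer:{k}": v for k, v in classifier.model.buffers().items()})
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported checkpoint format version {meta['format_version']}"
            )
        params = {k[6:]: data[k] for k in data.files if k.startswith("param:")}
        buffers = {k[7:]: data[k] for k in data.files if k.startswith("buffer:")}
    stats_raw = meta["stats"]
    stats = ChannelStats(
        mean=tuple(stats_raw["mean"]), std=tuple(stats_raw["std"]), eps=stats_raw["eps"]
    )
    config_raw = meta["config"]
    config = TrainingConfig(**config_raw)
    model = nn.build_model(meta["arch"], seed=config.seed)
    model.load_state(params, buffers)
    return TrainedClassifier(model=model, stats=stats, config=config)
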