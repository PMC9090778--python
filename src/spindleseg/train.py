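"""Training: generalized dice loss, by-subject k-fold CV, early stopping.

One training session fits the U-Net with Adam on minibatches of whole
segments, using the generalized dice loss on the raw (unsmoothed)
probability tracks; smoothing belongs to inference only. After each epoch
the model is applied to the validation fold and scored by the event-level
F1-bar (the threshold-integrated F1), which also drives model selection and
early stopping: training stops once the metric has not improved for
``patience`` epochs or at the epoch cap.

Folds are split by subject so no subject's segments straddle the
train/validation boundary, with ten-segment subjects dealt evenly across
folds first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .events import EventList
from .evaluate import f1_curve_and_bar
from .model import ModelConfig, SpindleUNet, build_model
from .postprocess import (
    events_to_indicator,
    indicator_to_events,
    smooth,
    to_indicator,
)
from .model import ProbabilityTrack
from .preprocess import EEGSegment

Sample = tuple[EEGSegment, EventList]


@dataclass
class TrainConfig:
    """Optimizer and schedule hyperparameters."""

    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 12
    patience: int = 300
    max_epochs: int = 800
    folds: int = 6
    val_metric: str = "f1_bar"  # or "f1_at_default"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainState:
    """Mutable bookkeeping for one training session."""

    fold_index: int = 0
    epoch: int = 0
    best_metric: float = -np.inf
    epochs_since_improvement: int = 0
    seed: int = 0


@dataclass
class FoldSplit:
    """Subject-to-fold assignment for cross-validation."""

    assignments: dict[str, int]
    k: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)


EPS_CLASS_WEIGHT = 1e-8


def generalized_dice_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Generalized dice loss over a batch of two-class probability tracks.

    ``probs`` and one-hot ``targets`` have shape (batch, 2, time). Class
    weights are the inverse squared class volumes, computed over the whole
    batch, with an epsilon floor guarding classes absent from the batch.
    The loss is 1 - 2 * (sum_l w_l sum_n r p) / (sum_l w_l sum_n (r + p)),
    which is 0 exactly at a perfect prediction and bounded by 1.
    """
    probs, targets, w = _gdl_terms(probs, targets)
    num = float((w * (targets * probs).sum(axis=(0, 2)).reshape(-1)).sum())
    den = float((w * (targets + probs).sum(axis=(0, 2)).reshape(-1)).sum())
    return 1.0 - 2.0 * num / den


def generalized_dice_grad(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Analytic gradient of the loss w.r.t. the probabilities."""
    probs, targets, w = _gdl_terms(probs, targets)
    num = (w * (targets * probs).sum(axis=(0, 2))).sum()
    den = (w * (targets + probs).sum(axis=(0, 2))).sum()
    # d/dp [1 - 2 num/den] = -2 (w_l r - w_l * num/den) / den
    w_b = w[None, :, None]
    return (-2.0 * (w_b * targets * den - w_b * num) / den**2).astype(probs.dtype)


def _gdl_terms(probs: np.ndarray, targets: np.ndarray):
    probs = np.asarray(probs)
    targets = np.asarray(targets)
    if probs.shape != targets.shape or probs.ndim != 3 or probs.shape[1] != 2:
        raise ValueError("expected matching (batch, 2, time) arrays")
    class_volume = targets.sum(axis=(0, 2))
    w = 1.0 / np.maximum(class_volume**2, EPS_CLASS_WEIGHT)
    return probs, targets, w


def init_params(network: SpindleUNet, seed: int) -> SpindleUNet:
    """Kaiming-uniform initialization of all conv weights, seeded."""
    nn.kaiming_uniform_(network, np.random.default_rng(seed))
    return network


def kfold_by_subject(subject_records: list[dict], k: int = 6, seed: int = 0) -> FoldSplit:
    """By-subject fold assignment with ten-segment subjects balanced first.

    Ten-segment subjects are shuffled and dealt round-robin so each fold
    receives an equal share; remaining subjects are shuffled and assigned to
    the currently smallest folds, keeping subject counts within one of each
    other (exactly equal when divisible).
    """
    if k > len(subject_records):
        raise ValueError(f"cannot make {k} folds from {len(subject_records)} subjects")
    rng = np.random.default_rng(seed)
    ten = sorted(r["subject_id"] for r in subject_records if r["n_segments"] >= 10)
    rest = sorted(r["subject_id"] for r in subject_records if r["n_segments"] < 10)
    rng.shuffle(ten)
    rng.shuffle(rest)
    assignments: dict[str, int] = {}
    counts = [0] * k
    for i, sid in enumerate(ten):
        assignments[sid] = i % k
        counts[i % k] += 1
    for sid in rest:
        fold = int(np.argmin(counts))
        assignments[sid] = fold
        counts[fold] += 1
    return FoldSplit(assignments=assignments, k=k)


def steps_per_epoch(n_segments: int, batch_size: int) -> int:
    """Minibatch count per epoch; the last short batch is kept."""
    return math.ceil(n_segments / batch_size)


def make_targets(samples: list[Sample]) -> np.ndarray:
    """One-hot (n, 2, T) labels from annotations; channel 1 is spindle."""
    T = len(samples[0][0].samples)
    out = np.zeros((len(samples), 2, T), dtype=nn.DTYPE)
    for i, (segment, events) in enumerate(samples):
        ind = events_to_indicator(events, T, segment.fs)
        out[i, 1] = ind
        out[i, 0] = 1 - ind
    return out


def _predict_batched(
    network: SpindleUNet, segments: list[EEGSegment], config: ModelConfig, batch: int
) -> list[EventList]:
    """Inference-mode event prediction for equal-length segments, batched."""
    nn.set_training(network, False)
    out: list[EventList] = []
    for i in range(0, len(segments), batch):
        chunk = segments[i : i + batch]
        x = np.stack([s.samples for s in chunk]).astype(nn.DTYPE)
        p = network.forward_batch(x)
        for j, seg in enumerate(chunk):
            track = ProbabilityTrack(
                spindle_prob=p[j, 1], no_spindle_prob=p[j, 0], fs=seg.fs
            )
            track = smooth(track, config.moving_avg_width)
            out.append(indicator_to_events(to_indicator(track), seg.fs))
    return out


def validation_metric(
    network: SpindleUNet,
    samples: list[Sample],
    model_config: ModelConfig,
    batch_size: int,
    metric: str = "f1_bar",
) -> float:
    detected = _predict_batched(
        network, [s for s, _ in samples], model_config, batch_size
    )
    reference = [e for _, e in samples]
    metrics = f1_curve_and_bar(detected, reference)
    return metrics.f1_bar if metric == "f1_bar" else metrics.f1


def train_fold(
    train_samples: list[Sample],
    val_samples: list[Sample],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    fold_index: int = 0,
) -> tuple[SpindleUNet, pd.DataFrame]:
    """Fit one model on the training fold, select the best epoch on the
    validation fold, and early-stop on the validation metric.

    Returns the network restored to its best-epoch parameters and a history
    frame with one row per epoch (mean loss, validation metric).
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    tc = train_config or TrainConfig()
    network = build_model(model_config)
    init_params(network, seed)
    optimizer = nn.Adam(
        network, lr=tc.learning_rate, beta1=tc.beta1, beta2=tc.beta2, eps=tc.epsilon
    )
    rng = np.random.default_rng(seed + 1)

    x_all = np.stack([s.samples for s, _ in train_samples]).astype(nn.DTYPE)
    y_all = make_targets(train_samples)
    n = len(train_samples)
    state = TrainState(fold_index=fold_index, seed=seed)
    best_state_dict = nn.state_dict(network)
    history = []

    for epoch in range(1, tc.max_epochs + 1):
        state.epoch = epoch
        order = rng.permutation(n)
        nn.set_training(network, True)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            probs = network.forward_batch(x_all[idx])
            losses.append(generalized_dice_loss(probs, y_all[idx]))
            network.backward_batch(generalized_dice_grad(probs, y_all[idx]))
            optimizer.step()
        metric = validation_metric(
            network, val_samples, model_config, tc.batch_size, tc.val_metric
        )
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_metric": metric}
        )
        if metric > state.best_metric:
            state.best_metric = metric
            state.epochs_since_improvement = 0
            best_state_dict = nn.state_dict(network)
        else:
            state.epochs_since_improvement += 1
        if state.epochs_since_improvement >= tc.patience:
            break

    nn.load_state_dict(network, best_state_dict)
    nn.set_training(network, False)
    return network, pd.DataFrame(history)


def cross_validate(
    samples_by_subject: dict[str, list[Sample]],
    subject_records: list[dict],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> dict:
    """Six-fold (by default) cross-validation: one best model per fold.

    Returns the per-fold models, histories, and the mean and standard
    deviation of the best validation F1-bar across folds.
    """
    tc = train_config or TrainConfig()
    split = kfold_by_subject(subject_records, k=tc.folds, seed=seed)
    models, histories, best_metrics = [], [], []
    for fold in range(tc.folds):
        val_ids = set(split.fold_subjects(fold))
        train_samples = [
            s
            for sid, lst in sorted(samples_by_subject.items())
            if sid not in val_ids
            for s in lst
        ]
        val_samples = [
            s
            for sid, lst in sorted(samples_by_subject.items())
            if sid in val_ids
            for s in lst
        ]
        network, history = train_fold(
            train_samples,
            val_samples,
            model_config,
            tc,
            seed=seed + fold,
            fold_index=fold,
        )
        models.append(network)
        histories.append(history)
        best_metrics.append(history["val_metric"].max())
    best = np.asarray(best_metrics, dtype=float)
    return {
        "models": models,
        "histories": histories,
        "split": split,
        "fold_metrics": best,
        "mean_metric": float(best.mean()),
        "sd_metric": float(best.std(ddof=1)),
    }
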