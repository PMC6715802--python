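"""Staged training with progressive unfreezing.

Patch classifiers start from a (possibly pre-trained) trunk and are trained
in three stages that progressively widen the trainable scope while lowering
the learning rate: last layer only, then the top weighted layers, then all
layers. Converted whole-image classifiers are trained in two stages: the
newly added top layers first, then everything end to end. Transfer to a new
acquisition platform is a single all-layer fine-tuning stage that consumes
image-level labels only.

The only preprocessing anywhere is subtraction of the training-set mean
gray value; per-batch sample weights equalize the five patch classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .models import NetworkHandle
from .patches import class_balance_weights

log = logging.getLogger(__name__)

_SCOPE_RANK = {"last_layer": 0, "top_n_layers": 1, "new_top_layers": 1, "all": 2}


class DataError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class Stage:
    learning_rate: float
    epochs: int
    scope: str                    # 'last_layer' | 'top_n_layers' | 'all' | 'new_top_layers'
    weight_decay: float = 0.0
    top_n: int | None = None      # weighted-layer count for 'top_n_layers'
    top_fraction: float = 0.3     # fallback scope for arbitrary backbones

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("each stage needs at least one epoch")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.scope not in _SCOPE_RANK:
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class StageSchedule:
    stages: list[Stage]

    def __post_init__(self):
        ranks = [_SCOPE_RANK[s.scope] for s in self.stages]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("unfreeze scopes must widen monotonically")

    @property
    def total_epochs(self) -> int:
        return sum(s.epochs for s in self.stages)


def patch_schedule_3stage(top_n: int | None = None,
                          epochs=(3, 10, 37)) -> StageSchedule:
    """Pre-trained patch schedule: 1e-3 last layer / 1e-4 top layers /
    1e-5 all layers, 50 epochs total. `top_n` presets: 46 weighted layers
    for the 50-layer residual net, 11 for the 16-layer VGG; otherwise the
    top 30% of weighted layers."""
    return StageSchedule([
        Stage(1e-3, epochs[0], "last_layer"),
        Stage(1e-4, epochs[1], "top_n_layers", top_n=top_n),
        Stage(1e-5, epochs[2], "all"),
    ])


TOP_N_PRESETS = {"Resnet50": 46, "VGG16": 11}


def patch_schedule_s1(top_n: int | None = None) -> StageSchedule:
    """S1 variant: total epochs raised to 200 for the smaller patch set."""
    return patch_schedule_3stage(top_n=top_n, epochs=(3, 10, 187))


def patch_schedule_random_init(epochs: int = 50) -> StageSchedule:
    """Randomly initialized networks: constant learning rate 1e-3."""
    return StageSchedule([Stage(1e-3, epochs, "all")])


def whole_image_schedule_2stage(epochs=(30, 20)) -> StageSchedule:
    """Train the new top layers (1e-4, weight decay 0.001), then all layers
    (1e-5, weight decay 0.01); 50 epochs total."""
    return StageSchedule([
        Stage(1e-4, epochs[0], "new_top_layers", weight_decay=0.001),
        Stage(1e-5, epochs[1], "all", weight_decay=0.01),
    ])


def desk_scale_patch_schedule() -> StageSchedule:
    """Three-stage schedule sized for CPU experiments on randomly
    initialized tiny backbones: the canonical rates assume an externally
    pre-trained trunk whose bottom layers must be protected, so the
    desk-scale preset keeps the progressive unfreezing structure but raises
    each stage's rate by an order of magnitude and shortens the stages."""
    return StageSchedule([
        Stage(1e-2, 2, "last_layer"),
        Stage(3e-3, 4, "top_n_layers"),
        Stage(1e-3, 8, "all"),
    ])


def desk_scale_whole_schedule() -> StageSchedule:
    """Two-stage whole-image schedule for CPU experiments (same structure
    and weight-decay pairing as the canonical one, shorter and faster)."""
    return StageSchedule([
        Stage(1e-3, 12, "new_top_layers", weight_decay=0.001),
        Stage(1e-4, 8, "all", weight_decay=0.01),
    ])


def vgg_extension_schedule(epochs: int = 200) -> StageSchedule:
    """Optional continuation for VGG-based image classifiers that are still
    improving at the end of the standard two stages."""
    return StageSchedule([Stage(1e-5, epochs, "all", weight_decay=0.01)])


@dataclass
class TrainConfig:
    batch_size: int = 32          # 2 is the whole-image default, set by callers
    mean_pixel: float = 0.0       # training-set mean, computed once
    seed: int = 0
    augment: bool = False
    balance_classes: bool = True

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not np.isfinite(self.mean_pixel):
            raise ValueError("mean_pixel must be finite")


def preprocess(images: np.ndarray, mean_pixel: float) -> np.ndarray:
    """Subtract the training-set mean gray value; no other normalization."""
    if not np.isfinite(mean_pixel):
        raise ValueError("mean_pixel must be finite")
    return np.asarray(images, dtype=np.float32) - np.float32(mean_pixel)


# ---------------------------------------------------------------------------
# Freeze scoping

def _set_scope(handle: NetworkHandle, stage: Stage):
    net = handle.net
    for lay in net.leaf_layers():
        lay.trainable = False
    if stage.scope == "all":
        for lay in net.leaf_layers():
            lay.trainable = True
        return
    if stage.scope == "new_top_layers":
        for lay in net.layers[handle.source_layer_count:]:
            lay.trainable = True
        return
    groups = nn.weighted_groups(net)
    if stage.scope == "last_layer":
        chosen = groups[-1:]
    else:
        n = stage.top_n or max(int(round(stage.top_fraction * len(groups))), 1)
        chosen = groups[-n:]
    for group in chosen:
        for lay in group:
            lay.trainable = True


def frozen_checksum(handle: NetworkHandle) -> float:
    """Fingerprint of all parameters currently outside the trainable scope."""
    total = 0.0
    for lay in handle.net.leaf_layers():
        if not getattr(lay, "trainable", False):
            for p in lay.params():
                total += float(np.abs(np.asarray(p.data, dtype=np.float64)).sum())
    return total


# ---------------------------------------------------------------------------
# Core loop

def _accuracy(handle, x, y, batch=256):
    preds = []
    for i in range(0, len(x), batch):
        preds.append(handle.net.forward(x[i:i + batch], train=False).argmax(axis=1))
    return float((np.concatenate(preds) == y).mean())


def _auc_metric(handle, x, y, batch=16):
    from .evaluate import roc_auc_values
    scores = []
    for i in range(0, len(x), batch):
        scores.append(handle.net.forward(x[i:i + batch], train=False)[:, 1])
    return roc_auc_values(np.concatenate(scores), y)


def _run_schedule(handle: NetworkHandle, xtr, ytr, schedule: StageSchedule,
                  config: TrainConfig, val=None, metric="accuracy",
                  stage_tag="stage") -> pd.DataFrame:
    if len(xtr) == 0:
        raise DataError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    n_classes = handle.n_classes
    history = []
    best = (-np.inf, None)
    epoch_counter = 0
    for si, stage in enumerate(schedule.stages):
        _set_scope(handle, stage)
        opt = nn.Adam(handle.net, lr=stage.learning_rate,
                      weight_decay=stage.weight_decay)
        for _ in range(stage.epochs):
            epoch_counter += 1
            order = rng.permutation(len(xtr))
            losses = []
            for i in range(0, len(order), config.batch_size):
                idx = order[i:i + config.batch_size]
                xb, yb = xtr[idx], ytr[idx]
                if config.augment:
                    xb = _augment_batch(xb, rng)
                onehot = np.eye(n_classes, dtype=np.float32)[yb]
                weights = (class_balance_weights(yb)
                           if config.balance_classes else None)
                probs = handle.net.forward(xb, train=True)
                loss, grad = nn.softmax_xent_grad(probs, onehot, weights)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"NaN/inf loss in {stage_tag} {si + 1} "
                        f"(epoch {epoch_counter})")
                opt.zero_grad()
                handle.net.backward(grad, start_after=len(handle.net.layers) - 1)
                opt.step()
                losses.append(loss)
            row = {"stage": si + 1, "epoch": epoch_counter,
                   "loss": float(np.mean(losses))}
            if val is not None:
                xv, yv = val
                score = (_accuracy(handle, xv, yv) if metric == "accuracy"
                         else _auc_metric(handle, xv, yv))
                row[f"val_{metric}"] = score
                # ties resolve to the later epoch: with small validation
                # sets the metric saturates while training still helps
                if score >= best[0]:
                    best = (score, nn.get_weights(handle.net))
            history.append(row)
    if best[1] is not None:
        nn.set_weights(handle.net, best[1])
    return pd.DataFrame(history)


def _augment_batch(xb, rng):
    from .patches import PatchRecord, augment
    out = np.empty_like(xb)
    for i in range(len(xb)):
        rec = PatchRecord(xb[i, 0], "background", "batch", (0, 0))
        out[i, 0] = augment(rec, rng).pixels
    return out


# ---------------------------------------------------------------------------
# Public entry points

def train_patch(handle: NetworkHandle, train_set, schedule: StageSchedule,
                config: TrainConfig, val_set=None
                ) -> tuple[NetworkHandle, pd.DataFrame]:
    """Train a 5-class patch classifier under a staged schedule.

    `train_set`/`val_set` are (pixels (N,1,p,p), labels (N,)) pairs in raw
    intensity units; the training-set mean subtraction uses
    `config.mean_pixel`. Weights outside each stage's scope are untouched;
    the best-validation-epoch weights are restored at the end.
    """
    xtr, ytr = train_set
    if len(xtr) == 0:
        raise DataError("empty patch dataset")
    if ytr.max() >= handle.n_classes:
        raise DataError("label outside the patch-class range")
    xtr = preprocess(xtr, config.mean_pixel)
    val = None
    if val_set is not None:
        val = (preprocess(val_set[0], config.mean_pixel), val_set[1])
    hist = _run_schedule(handle, xtr, ytr, schedule, config, val=val,
                         metric="accuracy", stage_tag="patch stage")
    return handle, hist


def train_whole(handle: NetworkHandle, image_set, schedule: StageSchedule,
                config: TrainConfig, val_set=None
                ) -> tuple[NetworkHandle, pd.DataFrame]:
    """Train a converted whole-image classifier (2-stage: new top layers,
    then end to end). Labels are binary (1 = malignant)."""
    if handle.kind != "whole_image":
        raise DataError("network was not produced by to_whole_image")
    xtr, ytr = image_set
    xtr = preprocess(xtr, config.mean_pixel)
    val = None
    if val_set is not None:
        val = (preprocess(val_set[0], config.mean_pixel), val_set[1])
    cfg = TrainConfig(batch_size=config.batch_size, mean_pixel=config.mean_pixel,
                      seed=config.seed, augment=config.augment,
                      balance_classes=False)
    hist = _run_schedule(handle, xtr, ytr, schedule, cfg, val=val,
                         metric="auc", stage_tag="whole-image stage")
    return handle, hist


def sample_patient_subset(patient_ids, labels, n_patients_subset: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Boolean row mask selecting all images of a patient-level subset that
    preserves the cohort's positive/negative patient ratio."""
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    unique = pd.unique(patient_ids)
    if n_patients_subset > len(unique):
        raise DataError(f"subset of {n_patients_subset} patients exceeds the "
                        f"{len(unique)} available")
    pat_label = {p: int(labels[patient_ids == p].max()) for p in unique}
    pos = np.array([p for p in unique if pat_label[p] == 1])
    neg = np.array([p for p in unique if pat_label[p] == 0])
    n_pos = int(round(n_patients_subset * len(pos) / len(unique)))
    n_pos = min(max(n_pos, 1 if len(pos) else 0), len(pos), n_patients_subset)
    n_neg = min(n_patients_subset - n_pos, len(neg))
    chosen = set(rng.choice(pos, n_pos, replace=False)) | \
        set(rng.choice(neg, n_neg, replace=False))
    return np.isin(patient_ids, list(chosen))


def finetune_transfer(handle: NetworkHandle, target_images, labels,
                      patient_ids, n_patients_subset: int,
                      config: TrainConfig, learning_rate: float = 1e-5,
                      epochs: int = 200, weight_decay: float = 0.01,
                      val_set=None) -> tuple[NetworkHandle, pd.DataFrame]:
    """Single-stage all-layer fine-tuning on a new platform using
    image-level labels only (no ROI masks enter this interface).

    A patient-level subset of `n_patients_subset` patients is drawn,
    preserving the cohort's label ratio; all images of a selected patient
    are used.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    sel = sample_patient_subset(patient_ids, labels, n_patients_subset, rng)
    target_images = np.asarray(target_images)
    schedule = StageSchedule([Stage(learning_rate, epochs, "all",
                                    weight_decay=weight_decay)])
    return train_whole(handle, (target_images[sel], labels[sel]), schedule,
                       config, val_set=val_set)
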