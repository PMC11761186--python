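"""Cohort preparation, tiling/augmentation, cross-validated training and
ensemble scoring.

The survival target is binary: 1 if overall survival is at least 36
months, else 0; only uncensored records enter label construction (their
event time is known exactly), censored records stay available for
Kaplan-Meier evaluation. Images are split into balanced folds (image- or
patient-level); per fold the training is repeated several times for a
fixed number of epochs, validation AUROC is checked after every epoch,
and the single best checkpoint across repeats x epochs is kept. The
ensemble H&E-based survival score of an image is the mean positive-class
probability across the selected fold models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .model import (AttentionNet, ModelConfig, FocalLossParams, build_model,
                    focal_loss, focal_loss_grad, standardize_tile, softmax)
from .nn.optim import Adam, StepDecay
from .survival import ValidationError, auroc

OS_TARGET_MONTHS = 36.0


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    learning_rate: float = 2e-4
    decay_factor: float = 0.1
    decay_epochs: int = 7
    epochs: int = 10
    repeats_per_fold: int = 5
    k_folds: int = 5
    batch_size: int = 6
    augment: bool = True
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.repeats_per_fold < 1 or self.k_folds < 2:
            raise ValidationError("epochs/repeats must be >= 1 and k_folds >= 2")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValidationError("learning rate and batch size must be positive")


def prepare_cohort(clinical: pd.DataFrame,
                   os_threshold: float = OS_TARGET_MONTHS):
    """Apply the inclusion rules and build survival labels.

    Stage I/II patients are excluded; a missing stage is imputed as III
    (so the record is retained). Labels are built from uncensored records
    only: target 1 iff OS >= ``os_threshold`` months.

    Returns (filtered clinical table, labels table with patient_id/target).
    """
    df = clinical.copy()
    stage = df["stage"].astype(object)
    stage = stage.where(~pd.isna(stage) & (stage != ""), "III")
    df["stage"] = stage
    df = df[~df["stage"].isin(["I", "II", 1, 2])].reset_index(drop=True)
    uncensored = df[df["os_event"] == 1]
    if uncensored["os_months"].isna().any():
        raise ValidationError("uncensored patient with missing OS duration")
    labels = pd.DataFrame({
        "patient_id": uncensored["patient_id"],
        "target": (uncensored["os_months"] >= os_threshold).astype(int),
    }).reset_index(drop=True)
    return df, labels


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[0] == size and image.shape[1] == size:
        return image
    return np.asarray(
        Image.fromarray(np.asarray(image, dtype=np.uint8))
        .resize((size, size), Image.BILINEAR))


def tile_image(image: np.ndarray, working_resolution: int = 1024) -> list[np.ndarray]:
    """Square input -> one tile; non-square -> two squares taken from the
    two ends of the long axis. All tiles are resized to the working
    resolution. Training consumes all tiles; validation/testing uses the
    first tile only."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("empty image")
    h, w = img.shape[0], img.shape[1]
    if h == w:
        return [_resize(img, working_resolution)]
    if w > h:
        tiles = [img[:, :h], img[:, w - h:]]
    else:
        tiles = [img[:w, :], img[h - w:, :]]
    return [_resize(t, working_resolution) for t in tiles]


def augment(image: np.ndarray, seed: int, normalize: bool = True) -> np.ndarray:
    """Seeded augmentation: horizontal/vertical flips (p=0.5 each), a
    multiple-of-90 rotation plus a small random angle (±15°), a random
    affine (shear and translation up to 10%), then per-channel
    standardization (skipped with ``normalize=False``)."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k)
    angle = rng.uniform(-15, 15)
    img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                         order=1, mode="reflect")
    h, w = img.shape[0], img.shape[1]
    shear = rng.uniform(-0.1, 0.1)
    ty, tx = rng.uniform(-0.1, 0.1, 2) * (h, w)
    matrix = np.array([[1.0, shear], [0.0, 1.0]])
    offset = np.array([ty, tx])
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = ndimage.affine_transform(img[:, :, c], matrix, offset=offset,
                                                order=1, mode="reflect")
    if not normalize:
        return np.clip(out, 0, 255).astype(np.uint8)
    chw = standardize_tile(out)
    return chw.transpose(1, 2, 0)


def make_folds(unit_ids, k: int, seed: int = 0,
               patient_of: dict | None = None) -> pd.DataFrame:
    """Random balanced k-fold partition of ``unit_ids``.

    With ``patient_of`` (unit -> patient) the partition is done at the
    patient level so no patient spans folds (the leakage-safe option);
    otherwise units are split directly (image-level, the reference
    protocol's choice). Returns a DataFrame (unit_id, fold).
    """
    unit_ids = list(unit_ids)
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if patient_of is None:
        if k > len(unit_ids):
            raise ValidationError("k exceeds the number of units")
        perm = rng.permutation(len(unit_ids))
        folds = np.empty(len(unit_ids), dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        return pd.DataFrame({"unit_id": unit_ids, "fold": folds})
    patients = sorted({patient_of[u] for u in unit_ids})
    if k > len(patients):
        raise ValidationError("k exceeds the number of patients")
    perm = rng.permutation(len(patients))
    p_fold = {}
    for f, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            p_fold[patients[i]] = f
    return pd.DataFrame({"unit_id": unit_ids,
                         "fold": [p_fold[patient_of[u]] for u in unit_ids]})


@dataclass
class FoldResult:
    model: AttentionNet
    auroc: float
    repeat: int
    epoch: int
    history: pd.DataFrame


def _snapshot(model: AttentionNet) -> list[np.ndarray]:
    from .nn.layers import BatchNorm2d

    arrays = [p.value.copy() for p in model.parameters()]
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            arrays.append(m.running_mean.copy())
            arrays.append(m.running_var.copy())
    return arrays


def _restore(model: AttentionNet, arrays: list[np.ndarray]) -> None:
    from .nn.layers import BatchNorm2d

    params = model.parameters()
    for p, a in zip(params, arrays):
        p.value = a.copy()
        p.grad = np.zeros_like(p.value)
    i = len(params)
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            m.running_mean = arrays[i].copy()
            m.running_var = arrays[i + 1].copy()
            i += 2


def predict_proba(model: AttentionNet, tiles: list[np.ndarray],
                  batch_size: int = 16) -> np.ndarray:
    """Evaluation-mode positive/negative probabilities for raw tiles."""
    model.eval()
    out = []
    for i in range(0, len(tiles), batch_size):
        batch = np.stack([standardize_tile(t) for t in tiles[i:i + batch_size]])
        out.append(model.forward_batch(batch).probabilities)
    return np.vstack(out)


def train_fold(train_images: list[np.ndarray], train_labels,
               val_images: list[np.ndarray], val_labels,
               model_config: ModelConfig, train_config: TrainConfig,
               fold_seed: int = 0) -> FoldResult:
    """Train ``repeats_per_fold`` independent models and return the
    checkpoint with the best validation AUROC across repeats x epochs
    (ties resolve to the earliest repeat/epoch).

    Training uses every tile of each image; validation uses the first
    tile only.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    val_labels = np.asarray(val_labels, dtype=int)
    if len(np.unique(val_labels)) < 2:
        raise ValidationError("validation fold must contain both classes")
    res = model_config.input_size
    tiles, tile_labels = [], []
    for img, lab in zip(train_images, train_labels):
        for t in tile_image(img, res):
            tiles.append(t)
            tile_labels.append(lab)
    tile_labels = np.asarray(tile_labels, dtype=int)
    val_tiles = [tile_image(img, res)[0] for img in val_images]

    best: tuple[float, int, int] | None = None
    best_arrays = None
    best_model: AttentionNet | None = None
    rows = []
    for rep in range(train_config.repeats_per_fold):
        rep_seed = (fold_seed * 1000 + rep * 7919) % (2 ** 31 - 1)
        model = build_model(model_config, seed=rep_seed)
        model.set_dropout_seed(rep_seed + 1)
        rng = np.random.default_rng(rep_seed + 2)
        opt = Adam(model.parameters(), lr=train_config.learning_rate)
        sched = StepDecay(opt, train_config.decay_epochs, train_config.decay_factor)
        for epoch in range(train_config.epochs):
            sched.at_epoch(epoch)
            model.train(True)
            order = rng.permutation(len(tiles))
            for i in range(0, len(order), train_config.batch_size):
                idx = order[i:i + train_config.batch_size]
                if train_config.augment:
                    batch = np.stack([
                        augment(tiles[j], int(rng.integers(2 ** 31 - 1))).transpose(2, 0, 1)
                        for j in idx])
                else:
                    batch = np.stack([standardize_tile(tiles[j]) for j in idx])
                targets = tile_labels[idx]
                out = model.forward_batch(batch.astype(np.float32))
                loss = focal_loss(out.probabilities, targets, train_config.focal)
                model.zero_grad()
                model.backward_batch(
                    focal_loss_grad(out.probabilities, targets,
                                    train_config.focal).astype(np.float32))
                opt.step()
            probs = predict_proba(model, val_tiles)
            val_auc = auroc(probs[:, 1], val_labels)
            rows.append({"repeat": rep, "epoch": epoch, "loss": loss,
                         "val_auroc": val_auc})
            if best is None or val_auc > best[0]:
                best = (val_auc, rep, epoch)
                best_arrays = _snapshot(model)
                best_model = model
    _restore(best_model, best_arrays)
    return FoldResult(best_model, best[0], best[1], best[2], pd.DataFrame(rows))


def ensemble_score(models: list[AttentionNet], image: np.ndarray,
                   positive_class: int = 1) -> float:
    """H&E-based survival score: mean positive-class probability of the
    selected fold models on the image's first tile."""
    if not models:
        raise ValidationError("need at least one model")
    res = models[0].config.input_size
    tile = tile_image(image, res)[0]
    probs = [predict_proba(m, [tile])[0, positive_class] for m in models]
    return float(np.mean(probs))


def ensemble_score_many(models: list[AttentionNet], images: dict,
                        positive_class: int = 1) -> pd.DataFrame:
    """Scores for a dict image_id -> image; returns (image_id, score)."""
    if not models:
        raise ValidationError("need at least one model")
    res = models[0].config.input_size
    ids = list(images)
    tiles = [tile_image(images[i], res)[0] for i in ids]
    acc = np.zeros(len(ids))
    for m in models:
        acc += predict_proba(m, tiles)[:, positive_class]
    return pd.DataFrame({"image_id": ids, "score": acc / len(models)})


def cross_validate(images: dict, labels: dict, model_config: ModelConfig,
                   train_config: TrainConfig,
                   patient_of: dict | None = None) -> list[FoldResult]:
    """Balanced k-fold split over image ids followed by per-fold training
    with best-AUROC checkpoint selection."""
    ids = sorted(images)
    folds = make_folds(ids, train_config.k_folds, seed=train_config.seed,
                       patient_of=patient_of)
    fold_of = dict(zip(folds["unit_id"], folds["fold"]))
    results = []
    for f in range(train_config.k_folds):
        tr = [i for i in ids if fold_of[i] != f]
        va = [i for i in ids if fold_of[i] == f]
        results.append(train_fold(
            [images[i] for i in tr], [labels[i] for i in tr],
            [images[i] for i in va], [labels[i] for i in va],
            model_config, train_config,
            fold_seed=train_config.seed * 100 + f))
    return results
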