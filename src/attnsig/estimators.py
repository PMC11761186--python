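"""scikit-learn style estimators over the attention classifier.

:class:`AttentionNetClassifier` is a plain fit/predict classifier for
image arrays; :class:`CrossValidatedEnsemble` runs the balanced k-fold
protocol with repeated training and best-AUROC checkpoint selection and
scores images with the fold-model ensemble. Both follow the sklearn
parameter conventions (constructor stores params verbatim, fitted
attributes end in an underscore, ``get_params``/``set_params`` work for
grid search); input validation is adapted to image batches rather than
2-D feature matrices.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .model import (ModelConfig, FocalLossParams, build_model, focal_loss,
                    focal_loss_grad, attention_heatmap)
from .nn.optim import Adam, StepDecay
from .pipeline import (TrainConfig, augment, cross_validate, predict_proba,
                       tile_image)
from .survival import ValidationError, auroc


def _as_image_list(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return [X[i] for i in range(X.shape[0])]
    images = list(X)
    for im in images:
        arr = np.asarray(im)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValidationError("each image must be (H, W, 3) RGB")
    return images


class AttentionNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier: attention-augmented CNN trained with focal loss.

    Parameters mirror the architecture/optimization settings; ``fit``
    expects images shaped (n, H, W, 3) (or a list of such arrays) and
    binary labels.
    """

    def __init__(self, backbone: str = "tiny", input_size: int = 64,
                 epochs: int = 10, learning_rate: float = 2e-4,
                 decay_factor: float = 0.1, decay_epochs: int = 7,
                 batch_size: int = 6, dropout_rate: float = 0.2,
                 gamma: float = 2.0, alpha: float = 0.25,
                 augment: bool = True, random_state: int = 0) -> None:
        self.backbone = backbone
        self.input_size = input_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.decay_epochs = decay_epochs
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.gamma = gamma
        self.alpha = alpha
        self.augment = augment
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        return ModelConfig(backbone=self.backbone, input_size=self.input_size,
                           batch_size=self.batch_size,
                           dropout_rate=self.dropout_rate)

    def fit(self, X, y) -> "AttentionNetClassifier":
        images = _as_image_list(X)
        y = np.asarray(y).astype(int)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be binary")
        self.classes_ = np.array([0, 1])
        cfg = self._model_config()
        model = build_model(cfg, seed=self.random_state)
        model.set_dropout_seed(self.random_state + 1)
        rng = np.random.default_rng(self.random_state + 2)
        tiles, labels = [], []
        for img, lab in zip(images, y):
            for t in tile_image(img, self.input_size):
                tiles.append(t)
                labels.append(lab)
        labels = np.asarray(labels)
        focal = FocalLossParams(self.gamma, self.alpha)
        opt = Adam(model.parameters(), lr=self.learning_rate)
        sched = StepDecay(opt, self.decay_epochs, self.decay_factor)
        history = []
        from .model import standardize_tile
        for epoch in range(self.epochs):
            sched.at_epoch(epoch)
            model.train(True)
            order = rng.permutation(len(tiles))
            losses = []
            for i in range(0, len(order), self.batch_size):
                idx = order[i:i + self.batch_size]
                if self.augment:
                    batch = np.stack([
                        augment(tiles[j], int(rng.integers(2 ** 31 - 1))).transpose(2, 0, 1)
                        for j in idx])
                else:
                    batch = np.stack([standardize_tile(tiles[j]) for j in idx])
                out = model.forward_batch(batch.astype(np.float32))
                losses.append(focal_loss(out.probabilities, labels[idx], focal))
                model.zero_grad()
                model.backward_batch(focal_loss_grad(
                    out.probabilities, labels[idx], focal).astype(np.float32))
                opt.step()
            history.append(float(np.mean(losses)))
        self.model_ = model
        self.loss_history_ = history
        self.n_features_in_ = 3
        return self

    def predict_proba(self, X) -> np.ndarray:
        images = _as_image_list(X)
        tiles = [tile_image(im, self.input_size)[0] for im in images]
        return predict_proba(self.model_, tiles)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def attention_maps(self, X) -> list[np.ndarray]:
        """Normalized module-2 attention heatmaps at image resolution."""
        return [attention_heatmap(self.model_, tile_image(im, self.input_size)[0])
                for im in _as_image_list(X)]


class CrossValidatedEnsemble(BaseEstimator):
    """Balanced k-fold training with repeated runs and best-AUROC
    selection; predictions are the fold-model ensemble's mean
    positive-class probability (the H&E-based survival score)."""

    def __init__(self, backbone: str = "tiny", input_size: int = 64,
                 k_folds: int = 5, repeats_per_fold: int = 5, epochs: int = 10,
                 learning_rate: float = 2e-4, decay_factor: float = 0.1,
                 decay_epochs: int = 7, batch_size: int = 6,
                 dropout_rate: float = 0.2, augment: bool = True,
                 random_state: int = 0) -> None:
        self.backbone = backbone
        self.input_size = input_size
        self.k_folds = k_folds
        self.repeats_per_fold = repeats_per_fold
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.decay_epochs = decay_epochs
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.augment = augment
        self.random_state = random_state

    def fit(self, X, y, groups=None) -> "CrossValidatedEnsemble":
        """``groups`` (per-image patient ids) switches the split to the
        leakage-safe patient level."""
        images = _as_image_list(X)
        y = np.asarray(y).astype(int)
        ids = [f"img{i:05d}" for i in range(len(images))]
        image_map = dict(zip(ids, images))
        label_map = dict(zip(ids, y))
        patient_of = dict(zip(ids, groups)) if groups is not None else None
        cfg = ModelConfig(backbone=self.backbone, input_size=self.input_size,
                          batch_size=self.batch_size,
                          dropout_rate=self.dropout_rate)
        tc = TrainConfig(learning_rate=self.learning_rate,
                         decay_factor=self.decay_factor,
                         decay_epochs=self.decay_epochs, epochs=self.epochs,
                         repeats_per_fold=self.repeats_per_fold,
                         k_folds=self.k_folds, batch_size=self.batch_size,
                         augment=self.augment, seed=self.random_state)
        results = cross_validate(image_map, label_map, cfg, tc,
                                 patient_of=patient_of)
        self.fold_models_ = [r.model for r in results]
        self.fold_aurocs_ = [r.auroc for r in results]
        self.fold_results_ = results
        return self

    def predict_score(self, X) -> np.ndarray:
        """Per-image ensemble survival score in [0, 1]."""
        images = _as_image_list(X)
        tiles = [tile_image(im, self.input_size)[0] for im in images]
        acc = np.zeros(len(tiles))
        for m in self.fold_models_:
            acc += predict_proba(m, tiles)[:, 1]
        return acc / len(self.fold_models_)

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1.0 - s, s])

    def score(self, X, y) -> float:
        """Validation-style AUROC of the ensemble score."""
        return auroc(self.predict_score(X), np.asarray(y).astype(int))
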