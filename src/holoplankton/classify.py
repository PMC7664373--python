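"""Classifier training, evaluation and max-voting ensembling.

Training follows a fixed fine-tuning-style protocol: mini-batch SGD
(learning rate 0.001, momentum 0.9, weight decay 0.001), center-cropped
inputs, early stopping after five epochs without a validation-loss
improvement (hard cap 200 epochs), and retention of the checkpoint with the
minimum validation loss.  Individual models are combined by max voting:
per sample, the modal predicted label wins; ties go to the label with the
highest mean confidence among its voters, then to the lowest class id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import SGDState, TinyCNN, softmax_cross_entropy
from .phase import TWO_PI

__all__ = [
    "TrainConfig",
    "ImageDataset",
    "TrainingLog",
    "TrainedModel",
    "PredictionSet",
    "ConfusionMatrix",
    "EvalResult",
    "train_model",
    "evaluate",
    "max_vote",
    "select_ensemble",
    "ensemble_predict",
    "early_stop_epoch",
    "ARCHITECTURES",
]

# Desk-scale architecture registry: name -> conv channel widths (one 2x
# max-pool per block).  Members of different widths stand in for the distinct
# deep families a GPU-scale run would fine-tune.
ARCHITECTURES: dict[str, tuple[int, ...]] = {
    "tiny_cnn": (8, 16),
    "tiny_cnn_narrow": (6, 12),
    "tiny_cnn_wide": (12, 24),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.001
    patience_epochs: int = 5
    max_epochs: int = 200
    crop_px: int = 224
    channel_replicate: bool = True
    batch_size: int = 64
    downsample: int = 1  # average-pool factor applied after the center crop
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not self.patience_epochs < self.max_epochs:
            raise ValueError("patience_epochs must be less than max_epochs")
        if self.downsample < 1:
            raise ValueError("downsample must be a positive integer")


@dataclass
class ImageDataset:
    """In-memory labeled image set.

    ``images``: (N, H, W) float array of wrapped phase in [-pi, pi) (or
    already-normalized gray values); ``labels``: integer class ids;
    ``class_ids``: the full ordered label set of the classification problem
    (a superset of the labels present).
    """

    images: np.ndarray
    labels: np.ndarray
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=int)
        self.class_ids = tuple(int(c) for c in self.class_ids)
        if self.images.ndim != 3 or len(self.labels) != len(self.images):
            raise ValueError("images must be (N, H, W) with one label per image")
        unknown = set(self.labels.tolist()) - set(self.class_ids)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in class_ids")

    def __len__(self) -> int:
        return len(self.images)

    @classmethod
    def from_manifest(
        cls,
        manifest: pd.DataFrame,
        images: np.ndarray,
        class_ids: tuple[int, ...] | None = None,
    ) -> "ImageDataset":
        """Select manifest rows (by index) out of a materialized image stack."""
        idx = manifest.index.to_numpy()
        labels = manifest["class_id"].to_numpy()
        if class_ids is None:
            class_ids = tuple(sorted(set(labels.tolist())))
        return cls(images=images[idx], labels=labels, class_ids=class_ids)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def val_losses(self) -> list[float]:
        return [e["val_loss"] for e in self.epochs]


@dataclass
class TrainedModel:
    """A trained network plus the label bookkeeping needed at test time."""

    name: str
    net: TinyCNN
    class_ids: tuple[int, ...]
    config: TrainConfig
    log: TrainingLog

    def predict(self, ds: ImageDataset) -> tuple[np.ndarray, np.ndarray]:
        """(predicted class ids, confidences) for every sample of ``ds``."""
        x = _preprocess(ds.images, self.config)
        proba = self.net.predict_proba(x)
        idx = proba.argmax(axis=1)
        ids = np.asarray(self.class_ids)[idx]
        conf = proba[np.arange(len(idx)), idx]
        return ids, conf


def _center_crop(images: np.ndarray, crop_px: int) -> np.ndarray:
    _, h, w = images.shape
    ch, cw = min(crop_px, h), min(crop_px, w)
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    return images[:, r0 : r0 + ch, c0 : c0 + cw]


def _preprocess(images: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Center crop, optionally downsample, map phase to gray in [0, 1]."""
    x = _center_crop(np.asarray(images, dtype=np.float32), config.crop_px)
    d = config.downsample
    if d > 1:
        n, h, w = x.shape
        h -= h % d
        w -= w % d
        x = x[:, :h, :w].reshape(n, h // d, d, w // d, d).mean(axis=(2, 4))
    x = (x + np.pi) / TWO_PI
    return x[:, None, :, :]  # single gray channel


def early_stop_epoch(val_losses: list[float], patience: int) -> tuple[int, int]:
    """Apply the early-stopping rule to a validation-loss sequence.

    Returns ``(best_epoch, stop_epoch)`` (0-based): the epoch with the
    minimum loss (first occurrence) and the epoch after which training
    stops — exactly ``patience`` epochs past the best one, or the last
    epoch if the patience budget is never exhausted.
    """
    best, stop = 0, len(val_losses) - 1
    for i in range(1, len(val_losses)):
        if val_losses[i] < val_losses[best]:
            best = i
        elif i - best >= patience:
            stop = i
            break
    else:
        return best, stop
    return best, stop


def train_model(
    train_ds: ImageDataset,
    val_ds: ImageDataset,
    architecture_name: str = "tiny_cnn",
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train a registered architecture under the fixed SGD protocol.

    After each epoch the full validation loss is computed; training stops
    once ``patience_epochs`` epochs pass without improvement (or at
    ``max_epochs``), and the parameters from the minimum-validation-loss
    epoch are restored into the returned model.  Deterministic for a fixed
    ``config.seed``.
    """
    if architecture_name not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture_name!r}; "
            f"registered: {sorted(ARCHITECTURES)}"
        )
    config = config or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if train_ds.class_ids != val_ds.class_ids:
        raise ValueError("train and validation class_ids differ")

    class_ids = train_ds.class_ids
    id_to_idx = {c: i for i, c in enumerate(class_ids)}
    y_train = np.array([id_to_idx[c] for c in train_ds.labels])
    y_val = np.array([id_to_idx[c] for c in val_ds.labels])
    x_train = _preprocess(train_ds.images, config)
    x_val = _preprocess(val_ds.images, config)

    net = TinyCNN(
        n_classes=len(class_ids),
        in_shape=x_train.shape[2:],
        channels=ARCHITECTURES[architecture_name],
        seed=config.seed,
    )
    state = SGDState(net.params)
    rng = np.random.default_rng(config.seed + 1)
    log = TrainingLog()
    best_loss = np.inf
    best_params = net.get_params()
    best_epoch = -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        train_losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = net.loss_and_grads(x_train[sel], y_train[sel])
            net.sgd_step(
                grads, state, config.learning_rate, config.momentum, config.weight_decay
            )
            train_losses.append(loss)
        logits = np.concatenate(
            [
                net.forward(x_val[i : i + 256])
                for i in range(0, len(x_val), 256)
            ]
        )
        val_loss, _, proba = softmax_cross_entropy(logits, y_val)
        val_acc = float((proba.argmax(axis=1) == y_val).mean())
        log.epochs.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = net.get_params()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience_epochs:
            break
    net.set_params(best_params)
    log.best_epoch = best_epoch
    log.stopped_epoch = log.epochs[-1]["epoch"]
    return TrainedModel(
        name=architecture_name, net=net, class_ids=class_ids, config=config, log=log
    )


@dataclass
class ConfusionMatrix:
    """Square confusion counts indexed by (true class, predicted class)."""

    counts: np.ndarray
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, true: np.ndarray, pred: np.ndarray, class_ids: tuple[int, ...]
    ) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(class_ids)}
        counts = np.zeros((len(class_ids), len(class_ids)), dtype=int)
        for t, p in zip(true, pred):
            counts[idx[int(t)], idx[int(p)]] += 1
        return cls(counts=counts, class_ids=tuple(class_ids))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def restrict(self, class_subset) -> "ConfusionMatrix":
        """Project onto a class subset (e.g. the classes present in a test set).

        Keeps only rows and columns of ``class_subset``; samples predicted
        outside the subset are dropped from the restricted view, mirroring a
        display that considers only test-set labels.
        """
        subset = [c for c in self.class_ids if c in set(class_subset)]
        pos = [self.class_ids.index(c) for c in subset]
        return ConfusionMatrix(
            counts=self.counts[np.ix_(pos, pos)], class_ids=tuple(subset)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_ids, columns=self.class_ids)


@dataclass
class EvalResult:
    accuracy: float
    confusion: ConfusionMatrix
    pred_labels: np.ndarray
    confidences: np.ndarray


def evaluate(model: TrainedModel, test_ds: ImageDataset) -> EvalResult:
    """Accuracy, confusion matrix and per-sample predictions on a test set.

    The confusion matrix spans the full trained label set (use
    :meth:`ConfusionMatrix.restrict` to display only test-set classes).

    Raises
    ------
    ValueError
        If the test set contains labels the model was not trained on.
    """
    unknown = set(test_ds.labels.tolist()) - set(model.class_ids)
    if unknown:
        raise ValueError(f"test labels {sorted(unknown)} unknown to the model")
    pred, conf = model.predict(test_ds)
    accuracy = float((pred == test_ds.labels).mean())
    cm = ConfusionMatrix.from_predictions(test_ds.labels, pred, model.class_ids)
    return EvalResult(accuracy=accuracy, confusion=cm, pred_labels=pred, confidences=conf)


def max_vote(
    per_model_labels: np.ndarray,
    per_model_confidences: np.ndarray | None = None,
) -> np.ndarray:
    """Max-voting combination of k models' predictions over n samples.

    ``per_model_labels``: (k, n) integer class ids.  Per sample the modal
    label wins; ties are broken by the highest mean confidence among the
    tied labels (mean over the models that voted for that label), then by
    the lowest class id.  With ``per_model_confidences=None`` all
    confidences are treated as equal.
    """
    labels = np.atleast_2d(np.asarray(per_model_labels, dtype=int))
    k, n = labels.shape
    if per_model_confidences is None:
        conf = np.ones_like(labels, dtype=float)
    else:
        conf = np.atleast_2d(np.asarray(per_model_confidences, dtype=float))
    if conf.shape != labels.shape:
        raise ValueError(
            f"confidence shape {conf.shape} does not match labels {labels.shape}"
        )
    voted = np.empty(n, dtype=int)
    for j in range(n):
        col, cj = labels[:, j], conf[:, j]
        uniq, counts = np.unique(col, return_counts=True)
        top = uniq[counts == counts.max()]
        if len(top) == 1:
            voted[j] = top[0]
            continue
        means = np.array([cj[col == lab].mean() for lab in top])
        best = np.flatnonzero(means == means.max())
        voted[j] = int(top[best].min())
    return voted


def ensemble_predict(models: list[TrainedModel], ds: ImageDataset) -> PredictionSet:
    """Run every model on ``ds`` and combine by max voting."""
    if not models:
        raise ValueError("ensemble requires at least one model")
    labels = np.stack([m.predict(ds)[0] for m in models])
    confs = np.stack([m.predict(ds)[1] for m in models])
    return PredictionSet(per_model_labels=labels, per_model_confidences=confs)


@dataclass
class PredictionSet:
    """Per-model predictions plus their max-voted combination."""

    per_model_labels: np.ndarray
    per_model_confidences: np.ndarray
    voted_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.per_model_labels = np.atleast_2d(np.asarray(self.per_model_labels, int))
        self.per_model_confidences = np.atleast_2d(
            np.asarray(self.per_model_confidences, float)
        )
        if self.per_model_confidences.shape != self.per_model_labels.shape:
            raise ValueError("label and confidence matrices must share a shape")
        if self.voted_labels is None:
            self.voted_labels = max_vote(
                self.per_model_labels, self.per_model_confidences
            )


def select_ensemble(
    model_results: list[tuple[str, float]], threshold: float = 0.90
) -> list[tuple[str, float]]:
    """Models with accuracy strictly greater than ``threshold``.

    Warns (does not raise) when no model clears the bar.
    """
    if not model_results:
        raise ValueError("model_results must be nonempty")
    selected = [(name, acc) for name, acc in model_results if acc > threshold]
    if not selected:
        warnings.warn(
            f"no model exceeded the accuracy threshold {threshold:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return selected
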