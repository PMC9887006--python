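"""Training of binary-weight single-layer classifiers.

Weights are binarized with the straight-through-estimator recipe:
real-valued latent weights are kept in [-1, 1], the forward pass uses
``sign(latent)``, and gradients flow straight through the sign wherever
``|latent| <= 1``.  The default loss is per-neuron sigmoid + binary
cross-entropy against one-vs-rest targets (a softmax + cross-entropy
mode is available); the optimizer is plain mini-batch SGD.  At export,
a latent weight of exactly 0 binarizes to +1 so that the emitted model
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .bnn import BNNModel, ImageSample

__all__ = ["TrainConfig", "BinaryDenseClassifier", "train_binary", "split_dataset"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: 30 epochs, learning rate 0.001, sigmoid activation with
    binary cross-entropy, mini-batch 64, 85/15 train/validation split.
    """

    epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 64
    seed: int = 0
    split_fraction: float = 0.85
    loss: str = "bce"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("bce", "softmax"):
            raise ValueError("loss must be 'bce' or 'softmax'")


def _sign_pm1(latent: np.ndarray) -> np.ndarray:
    """Binarize latent weights; exact zeros go to +1."""
    return np.where(latent >= 0.0, 1, -1).astype(np.int8)


class BinaryDenseClassifier(BaseEstimator, ClassifierMixin):
    """Single dense layer with straight-through-estimator binary weights.

    scikit-learn estimator API: ``fit(X, y)`` / ``predict(X)`` /
    ``decision_function(X)``; composes with pipelines and model
    selection.  ``X`` holds signed pixel levels (rows are flattened
    images), ``y`` arbitrary hashable class labels.

    Parameters
    ----------
    epochs, learning_rate, batch_size, loss :
        See :class:`TrainConfig`; same defaults.
    init_scale : float
        Half-width of the uniform latent-weight initialization.
    random_state : int or None
        Seed for initialization and per-epoch shuffling; fixing it
        makes training bit-reproducible.

    Attributes
    ----------
    classes_ : ndarray of sorted class labels.
    weights_ : (n_classes, n_features) int8 matrix of +/-1 weights.
    latent_weights_ : the underlying real-valued weights in [-1, 1].
    n_features_in_ : int
    """

    def __init__(
        self,
        epochs: int = 30,
        learning_rate: float = 0.001,
        batch_size: int = 64,
        loss: str = "bce",
        init_scale: float = 0.05,
        random_state: int | None = None,
    ) -> None:
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.loss = loss
        self.init_scale = init_scale
        self.random_state = random_state

    def fit(self, X, y) -> "BinaryDenseClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training needs at least 2 classes")
        if self.loss not in ("bce", "softmax"):
            raise ValueError("loss must be 'bce' or 'softmax'")
        n, p = X.shape
        c = self.classes_.size
        targets = (y[:, None] == self.classes_[None, :]).astype(np.float64)

        rng = np.random.default_rng(self.random_state)
        latent = rng.uniform(-self.init_scale, self.init_scale, size=(c, p))
        lr = self.learning_rate
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, tb = X[idx], targets[idx]
                z = xb @ _sign_pm1(latent).T.astype(np.float64)
                if self.loss == "bce":
                    prob = 1.0 / (1.0 + np.exp(-z))
                else:
                    z = z - z.max(axis=1, keepdims=True)
                    e = np.exp(z)
                    prob = e / e.sum(axis=1, keepdims=True)
                # dL/dz for both losses is (prob - target); mean over batch
                grad = (prob - tb).T @ xb / len(idx)
                # straight-through: pass gradient only where |latent| <= 1
                latent -= lr * grad * (np.abs(latent) <= 1.0)
                np.clip(latent, -1.0, 1.0, out=latent)
        self.latent_weights_ = latent
        self.weights_ = _sign_pm1(latent)
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.int64)
        return X @ self.weights_.T.astype(np.int64)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def to_model(self) -> BNNModel:
        """Export the fitted weights as an inference-side :class:`BNNModel`."""
        return BNNModel(self.weights_, tuple(self.classes_.tolist()))


def train_binary(dataset, n_classes: int | None = None, cfg: TrainConfig | None = None) -> BNNModel:
    """Train a binary-weight classifier on a dataset of image samples.

    ``dataset`` is anything with a ``samples`` sequence of
    :class:`~acidbase.bnn.ImageSample` (or such a sequence directly),
    each carrying a true label.
    """
    cfg = cfg or TrainConfig()
    samples = list(getattr(dataset, "samples", dataset))
    if not samples:
        raise ValueError("cannot train on an empty dataset")
    X = np.stack([s.levels for s in samples])
    y = np.asarray([s.true_label for s in samples])
    if n_classes is not None and np.unique(y).size != n_classes:
        raise ValueError(
            f"dataset has {np.unique(y).size} classes, expected {n_classes}"
        )
    clf = BinaryDenseClassifier(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        loss=cfg.loss,
        random_state=cfg.seed,
    ).fit(X, y)
    return clf.to_model()


def split_dataset(dataset, fraction: float = 0.85, seed: int = 0):
    """Random disjoint, exhaustive train/validation split (default 85/15).

    Returns two lists of samples; the train side gets
    ``round(n * fraction)`` samples.  Reproducible for a given seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    samples = list(getattr(dataset, "samples", dataset))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(len(samples) * fraction))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val
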