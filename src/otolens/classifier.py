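"""scikit-learn style facade over the introspectable CNN."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import network
from .network import NetworkModel, TrainConfig


class OtolithAgeClassifier(ClassifierMixin, BaseEstimator):
    """Miniature VGG-style age classifier with fit/predict semantics.

    ``X`` is a stack of grayscale images ``(n, H, W)`` with values in
    [0, 1]; ``y`` the integer read ages.  Normalization statistics are
    learned from the training images and reapplied at prediction time.
    The fitted network (``model_``) exposes every layer's weights and
    activations, which is what the relevance engine consumes.

    Parameters mirror the study recipe: Adam, batch size 8, learning
    rate 4e-4, cross-entropy, on-the-fly rotation/flip/shift
    augmentation.  The epoch count is problem-size dependent.
    """

    def __init__(self, conv_channels: tuple[int, ...] = (8, 16),
                 dense_units: int = 64, epochs: int = 10,
                 batch_size: int = 8, learning_rate: float = 4e-4,
                 augment: bool = True, random_state: int = 0):
        self.conv_channels = conv_channels
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.augment = augment
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_samples, size, size) square images")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        model = network.build_model(
            input_size=X.shape[1],
            class_labels=[int(c) for c in self.classes_],
            conv_channels=tuple(self.conv_channels),
            dense_units=self.dense_units,
            seed=self.random_state,
        )
        cfg = TrainConfig(batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          epochs=self.epochs, seed=self.random_state,
                          augment=self.augment)
        self.model_, self.history_ = network.train(model, X, y, cfg)
        return self

    def _normalized(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return network.normalize(X, self.model_.normalization_stats)

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return network.forward(self.model_, self._normalized(X)).logits

    def predict(self, X):
        """Argmax age; logit ties resolve toward the lowest age."""
        check_is_fitted(self, "model_")
        return network.predict_batch(self.model_, self._normalized(X))

    def predict_proba(self, X):
        return network.softmax(self.decision_function(X))

    @classmethod
    def from_model(cls, model: NetworkModel) -> "OtolithAgeClassifier":
        """Wrap an already-trained :class:`NetworkModel` (e.g. from a
        checkpoint)."""
        est = cls()
        est.model_ = model
        est.classes_ = np.asarray(model.class_labels)
        est.history_ = []
        return est
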