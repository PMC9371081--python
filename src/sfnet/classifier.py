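"""sklearn-style estimator facade over the two-stream network.

``SFNetClassifier`` takes a stack of grey images (n, H, W) in [0, 1] and
string or integer labels; internally it resizes to the configured input side,
precomputes improved-Canny edge maps for the edge stream, builds the network
and runs the seeded training loop. It follows the sklearn estimator contract
(get_params/set_params, fitted attributes with trailing underscores,
``classes_``, predict/predict_proba/score) and so composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .canny import ImprovedCannyEdgeDetector
from .image_io import ValidationError, resize_to
from .model import LRNParams, SFNetConfig, build_sfnet, count_parameters
from .training import TrainConfig, evaluate_arrays, fit_arrays


class SFNetClassifier(BaseEstimator, ClassifierMixin):
    """Two-stream fracture/healthy image classifier.

    Parameters mirror the architecture and training configuration; see
    ``SFNetConfig`` and ``TrainConfig``. ``use_edge_stream=False`` trains the
    grey-only ablation. ``random_state`` seeds weight init, shuffling and
    dropout.
    """

    def __init__(
        self,
        input_side: int = 256,
        input_channels: int = 3,
        conv_widths: tuple[int, ...] = (16, 32, 64, 128, 256, 512),
        kernel_side: int = 3,
        dense_units: int = 1024,
        dropout_rate: float = 0.5,
        lrn_n: int = 5,
        use_edge_stream: bool = True,
        edge_window: int = 3,
        edge_ratio: float = 0.5,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        self.input_side = input_side
        self.input_channels = input_channels
        self.conv_widths = conv_widths
        self.kernel_side = kernel_side
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.lrn_n = lrn_n
        self.use_edge_stream = use_edge_stream
        self.edge_window = edge_window
        self.edge_ratio = edge_ratio
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _config(self) -> SFNetConfig:
        return SFNetConfig(
            input_side=self.input_side,
            input_channels=self.input_channels,
            conv_widths=tuple(self.conv_widths),
            kernel_side=self.kernel_side,
            dense_units=self.dense_units,
            dropout_rate=self.dropout_rate,
            lrn=LRNParams(n=self.lrn_n),
        )

    def _prepare(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValidationError(f"X must be a (n, H, W) image stack, got shape {X.shape}")
        grey = np.stack([resize_to(im, self.input_side) for im in X]).astype(np.float32)
        edges = None
        if self.use_edge_stream:
            det = ImprovedCannyEdgeDetector(window=self.edge_window, ratio=self.edge_ratio)
            edges = det.transform(grey).astype(np.float32)
        return grey, edges

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[idx], y):
            raise ValidationError(f"labels outside fitted classes {self.classes_}")
        return idx.astype(np.int64)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "SFNetClassifier":
        """Train on (n, H, W) images with two-class labels.

        An optional validation set enables best-checkpoint retention and the
        ``val_loss``/``val_acc`` history entries.
        """
        self.classes_ = np.unique(np.asarray(y))
        if len(self.classes_) != 2:
            raise ValidationError(f"exactly two classes required, got {self.classes_}")
        grey, edges = self._prepare(X)
        y_idx = self._encode(y)
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
            seed=self.random_state,
        )
        self.model_ = build_sfnet(
            self._config(), seed=self.random_state, use_edge_stream=self.use_edge_stream
        )
        vg = ve = vy = None
        if X_val is not None and y_val is not None:
            vg, ve = self._prepare(X_val)
            vy = self._encode(y_val)
        self.history_ = fit_arrays(
            self.model_, grey, edges, y_idx, cfg,
            val_grey=vg, val_edges=ve, val_y=vy,
        )
        self.n_parameters_ = count_parameters(self.model_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        grey, edges = self._prepare(X)
        probs = []
        for lo in range(0, len(grey), 64):
            sl = slice(lo, lo + 64)
            probs.append(
                self.model_.predict_proba(grey[sl], None if edges is None else edges[sl])
            )
        return np.concatenate(probs)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        check_is_fitted(self, "model_")
        grey, edges = self._prepare(X)
        _, acc = evaluate_arrays(self.model_, grey, edges, self._encode(np.asarray(y)))
        return acc
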