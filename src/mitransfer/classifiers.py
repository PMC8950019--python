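"""Classifiers for CSP-featured motor-imagery trials.

Three models:

* :class:`CSPFeatureCNN` — the proposed classifier: each normalized
  log-variance feature vector is reshaped row-major into a small square grid
  (zero-padded) and fed to a 2-layer convolutional network (conv-ReLU-maxpool
  twice, then a fully connected 2-way softmax) trained with plain SGD.
* :class:`CSPSVM` — the classical baseline: a support-vector machine on the
  raw (unreshaped) feature vectors.
* :class:`FineTuneCNN` — a deep-transfer baseline that works on the raw
  trial matrices rendered to a fixed-size image: pretrain on the source
  domain, freeze the first convolutional layers, and retrain the head on a
  little labeled target data.

All CNN training is deterministic given the seed (fixed initialization and
per-epoch data order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "FeatureGrid",
    "CNNConfig",
    "reshape_features",
    "grid_side_for",
    "CSPFeatureCNN",
    "CSPSVM",
    "FineTuneCNN",
    "DEEP_FT_ARCH",
    "SMALL_FT_ARCH",
    "train_cnn",
    "train_svm_baseline",
    "train_ftcnn_baseline",
    "predict",
]


@dataclass
class FeatureGrid:
    """A feature vector reshaped to a 2D grid for the CNN."""

    grid: np.ndarray
    pad_count: int


@dataclass
class CNNConfig:
    """Hyperparameters of the proposed CNN.

    Defaults are learning rate 0.4, 160 epochs, batch size 1.  The learning
    rate is unusually large for SGD with cross-entropy; it works on the small
    feature grids used here but is freely overridable (the pipeline defaults
    to a smaller, more stable rate).
    """

    conv_channels: tuple = (8, 16)
    kernel_size: int = 3
    pool_size: int = 2
    learning_rate: float = 0.4
    epochs: int = 160
    batch_size: int = 1
    seed: int = 0
    grid_side: int | None = None  # None -> smallest square that fits

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size >= 1 and learning_rate > 0 required")


def grid_side_for(n_features: int) -> int:
    """Smallest g with g*g >= n_features."""
    return int(np.ceil(np.sqrt(n_features)))


def reshape_features(fv: np.ndarray, grid_side: int) -> FeatureGrid:
    """Row-major reshape of a feature vector into a grid, zero-padded.

    Flattening the grid and dropping the padding recovers the vector
    exactly.
    """
    fv = np.asarray(fv, dtype=np.float64).ravel()
    cap = grid_side * grid_side
    if cap < fv.size:
        raise ValueError(
            f"grid {grid_side}x{grid_side} too small for {fv.size} features"
        )
    pad = cap - fv.size
    grid = np.concatenate([fv, np.zeros(pad)]).reshape(grid_side, grid_side)
    return FeatureGrid(grid=grid, pad_count=pad)


class CSPFeatureCNN(ClassifierMixin, BaseEstimator):
    """The proposed small 2D CNN over reshaped CSP features.

    ``fit(X, y)`` takes feature vectors (n_samples, n_features) and binary
    labels; vectors are reshaped into ``grid_side`` x ``grid_side`` grids
    (default: the smallest square that fits, avoiding training on mostly
    structural zeros) and classified by two conv-ReLU-maxpool stages plus a
    fully connected softmax pair.

    Attributes
    ----------
    classes_ : ndarray of the two class values
    training_log_ : list of per-epoch mean cross-entropy losses
    network_ : the underlying layer stack
    grid_side_ : grid side actually used
    """

    def __init__(self, grid_side=None, conv_channels=(8, 16), kernel_size=3,
                 pool_size=2, learning_rate=0.4, epochs=160, batch_size=1,
                 seed=0):
        self.grid_side = grid_side
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: CNNConfig) -> "CSPFeatureCNN":
        return cls(
            grid_side=cfg.grid_side, conv_channels=cfg.conv_channels,
            kernel_size=cfg.kernel_size, pool_size=cfg.pool_size,
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=cfg.seed,
        )

    def _build(self, g: int, rng) -> nn.Network:
        c1, c2 = self.conv_channels
        p = self.pool_size
        side = (g // p) // p
        if side < 1:
            raise ValueError(
                f"grid side {g} too small for two {p}x{p} pooling stages"
            )
        return nn.Network([
            nn.Conv2D(1, c1, self.kernel_size, padding="same", rng=rng),
            nn.ReLU(),
            nn.MaxPool2D(p),
            nn.Conv2D(c1, c2, self.kernel_size, padding="same", rng=rng),
            nn.ReLU(),
            nn.MaxPool2D(p),
            nn.Flatten(),
            nn.Dense(c2 * side * side, 2, rng=rng),
        ])

    def _to_grids(self, X, g: int) -> np.ndarray:
        return np.stack(
            [reshape_features(x, g).grid for x in X]
        )[:, None, :, :]

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("expected (n_samples, n_features)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        g = self.grid_side or grid_side_for(X.shape[1])
        grids = self._to_grids(X, g)
        y_idx = (y == classes[1]).astype(int)
        rng = np.random.default_rng(self.seed)
        net = self._build(g, rng)
        self.training_log_ = nn.sgd_train(
            net, grids, y_idx, lr=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, rng=rng,
        )
        self.network_ = net
        self.classes_ = classes
        self.grid_side_ = g
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model fitted on {self.n_features_in_} features, got {X.shape[1]}"
            )
        grids = self._to_grids(X, self.grid_side_)
        return self.network_.predict_proba(grids)

    def predict(self, X):
        proba = self.predict_proba(X)
        check_is_fitted(self, "classes_")
        if proba.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.classes_[proba.argmax(axis=1)]


class CSPSVM(ClassifierMixin, BaseEstimator):
    """SVM baseline on raw CSP feature vectors (thin wrapper over SVC)."""

    def __init__(self, kernel="rbf", C=1.0, gamma="scale"):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.unique(y).size != 2:
            raise ValueError("need exactly 2 classes")
        self.svc_ = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                        random_state=0)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(np.asarray(X, dtype=np.float64))


# Deep fine-tuning baseline architectures: (layer kind, *options).
# DEEP_FT_ARCH is a six-conv / five-pool stack sized for 250x250 renders;
# SMALL_FT_ARCH is a scaled-down variant for small rendered inputs.
DEEP_FT_ARCH = (
    ("conv", 32, 11, 1), ("pool", 2),
    ("conv", 32, 11, 1), ("conv", 32, 11, 1), ("pool", 2),
    ("conv", 64, 7, 1), ("pool", 2),
    ("conv", 128, 3, 1), ("pool", 2),
    ("conv", 128, 3, 1), ("pool", 2),
    ("fc", 2048),
)
SMALL_FT_ARCH = (
    ("conv", 4, 3, "same"), ("pool", 2),
    ("conv", 8, 3, "same"), ("pool", 2),
    ("fc", 32),
)


class FineTuneCNN(ClassifierMixin, BaseEstimator):
    """Fine-tuning CNN baseline on rendered trial images.

    Each (channels x samples) trial is rendered to a square single-channel
    image of side ``input_size`` by bilinear resampling and scaled by the
    global standard deviation of the pretraining set (amplitude carries the
    class information, so no per-image standardization).  ``fit`` pretrains
    on source trials; :meth:`fine_tune` freezes the first ``freeze_depth``
    parameterized layers and retrains the rest on labeled target trials.

    Parameters
    ----------
    arch : sequence of layer specs
        ("conv", out_channels, kernel, padding) / ("pool", k) / ("fc", units).
        Default is the deep stack (250x250 input); use ``SMALL_FT_ARCH``
        with a small ``input_size`` for quick runs.
    freeze_depth : int, default 5
        Number of leading parameterized layers frozen during fine-tuning.
    """

    def __init__(self, arch=DEEP_FT_ARCH, input_size=250, freeze_depth=5,
                 learning_rate=0.01, epochs=10, finetune_epochs=10,
                 batch_size=8, seed=0):
        self.arch = arch
        self.input_size = input_size
        self.freeze_depth = freeze_depth
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.seed = seed

    def _shape(self):
        s = self.input_size
        return (s, s) if np.isscalar(s) else (int(s[0]), int(s[1]))

    def build_network(self, rng=None) -> nn.Network:
        """Instantiate the layer stack (ending in a 2-way softmax head)."""
        rng = rng or np.random.default_rng(self.seed)
        layers = []
        channels = 1
        h, w = self._shape()
        for spec in self.arch:
            kind = spec[0]
            if kind == "conv":
                _, out_c, k, pad = spec
                layers += [nn.Conv2D(channels, out_c, k, padding=pad, rng=rng),
                           nn.ReLU()]
                p = k // 2 if pad == "same" else int(pad)
                h = h + 2 * p - k + 1
                w = w + 2 * p - k + 1
                channels = out_c
            elif kind == "pool":
                _, k = spec
                layers.append(nn.MaxPool2D(k))
                h, w = h // k, w // k
            elif kind == "fc":
                _, units = spec
                layers += [nn.Flatten(),
                           nn.Dense(channels * h * w, units, rng=rng),
                           nn.ReLU()]
                channels, h, w = units, 1, 1
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
            if h < 1 or w < 1:
                raise ValueError("architecture shrinks the image below 1x1")
        layers.append(nn.Dense(channels * h * w, 2, rng=rng))
        return nn.Network(layers)

    def _render(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        h, w = self._shape()
        out = np.empty((X.shape[0], 1, h, w))
        for i, x in enumerate(X):
            zoom = (h / x.shape[0], w / x.shape[1])
            out[i, 0] = ndimage.zoom(x, zoom, order=1, grid_mode=True,
                                     mode="nearest")
        return out

    def fit(self, X, y):
        """Pretrain on the source domain."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly 2 classes")
        imgs = self._render(X)
        self.scale_ = float(imgs.std()) or 1.0
        imgs = imgs / self.scale_
        rng = np.random.default_rng(self.seed)
        net = self.build_network(rng)
        y_idx = (y == classes[1]).astype(int)
        self.training_log_ = nn.sgd_train(
            net, imgs, y_idx, lr=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, rng=rng,
        )
        self.network_ = net
        self.classes_ = classes
        return self

    def fine_tune(self, X, y):
        """Freeze the leading layers and retrain the rest on target data."""
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.network_.freeze_first(self.freeze_depth)
        imgs = self._render(X) / self.scale_
        y_idx = (y == self.classes_[1]).astype(int)
        rng = np.random.default_rng(self.seed + 1)
        self.finetune_log_ = nn.sgd_train(
            self.network_, imgs, y_idx, lr=self.learning_rate,
            epochs=self.finetune_epochs, batch_size=self.batch_size, rng=rng,
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        imgs = self._render(X) / self.scale_
        return self.network_.predict_proba(imgs)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers


def train_cnn(features, labels, cfg: CNNConfig) -> CSPFeatureCNN:
    """Train the proposed CNN on feature vectors (or FeatureGrid list)."""
    if features and isinstance(features[0], FeatureGrid):
        g = features[0].grid.shape[0]
        features = [fg.grid.ravel() for fg in features]
        cfg = CNNConfig(**{**cfg.__dict__, "grid_side": g})
    X = np.asarray(features, dtype=np.float64)
    return CSPFeatureCNN.from_config(cfg).fit(X, np.asarray(labels))


def predict(model, features):
    """Labels and normalized class scores for a batch of inputs."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] == 0:
        return model.classes_[:0], np.empty((0, 2))
    labels = model.predict(X)
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)
    else:  # margin classifiers: derive scores from the decision function
        d = model.svc_.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-d))
        scores = np.column_stack([1 - p1, p1])
    return labels, scores


def train_svm_baseline(features, labels, kernel="rbf", C=1.0,
                       gamma="scale") -> CSPSVM:
    return CSPSVM(kernel=kernel, C=C, gamma=gamma).fit(
        np.asarray(features, dtype=np.float64), np.asarray(labels)
    )


def train_ftcnn_baseline(source, target_train, **kwargs) -> FineTuneCNN:
    """Pretrain on a labeled source TrialSet, fine-tune on target trials."""
    model = FineTuneCNN(**kwargs)
    model.fit(source.as_array(), source.labels)
    if len(target_train):
        model.fine_tune(target_train.as_array(), target_train.labels)
    return model
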