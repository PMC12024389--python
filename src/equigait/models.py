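"""The eight gait-classification architectures behind one estimator interface.

Each architecture maps a scaled window of shape (L, 3) — L samples of
tri-axial acceleration — to a 4-way gait distribution (halt, walk, trot,
canter).  The roster:

``mlp``
    Flattened input → dense 128 → dense 64 → 4 outputs.
``cnn``
    Two 1-D conv layers of 8 filters, max pooling, a third conv of 8 filters,
    dropout, then a dense layer of 28 hidden and 4 output neurons.
``dilated_cnn``
    Same shape with 7 filters and dilated convolutions (rates 1, 2, 4) and a
    42-neuron hidden dense layer.
``spatial_dropout_cnn``
    Four conv layers of 120 filters, kernel 15, doubling dilations, each
    followed by 5% spatial (whole-channel) dropout, then an LSTM of 256 cells
    and a 512-neuron dense layer.
``lstm_small`` / ``lstm_large``
    Two stacked LSTM layers of 4 (resp. 32) cells, dropout, dense head.
``wavenet``
    Gated dilated causal convolutions with residual and skip connections
    (see :class:`equigait.nn.WaveNet`).
``conv_lstm``
    One convolutional LSTM layer with 8 filters, (1, 1) kernels and (1, 1)
    stride, dropout 0.5, then a dense layer of 64 hidden and 4 output
    neurons.  The window is laid out the usual way for convolutional LSTMs
    on inertial data: 4 recurrent sub-sequence steps over a (1 × L/4)
    spatial grid of 3-channel samples, so the (1, 1)-kernel gates act as a
    position-wise LSTM with shared weights (see
    :class:`equigait.nn.ConvLSTM1x1`).

Kernel sizes not pinned down by the roster use kernel 3; all are
overridable through ``hyperparams``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import (
    LSTM,
    Adam,
    Conv1D,
    ConvLSTM1x1,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool1D,
    MaxPool1D,
    ReLU,
    Sequential,
    SpatialDropout1D,
    WaveNet,
    softmax,
    softmax_xent,
)
from .preprocessing import SUPERCLASSES, WindowedDataset

__all__ = [
    "ARCH_IDS",
    "ModelSpec",
    "TrainConfig",
    "GaitNetClassifier",
    "build_model",
    "count_parameters",
    "train_model",
    "predict",
]

ARCH_IDS: tuple[str, ...] = (
    "mlp",
    "cnn",
    "dilated_cnn",
    "spatial_dropout_cnn",
    "lstm_small",
    "lstm_large",
    "wavenet",
    "conv_lstm",
)


@dataclass
class ModelSpec:
    """Resolved architecture description plus its trainable parameter count."""

    arch_id: str
    input_len: int
    n_channels: int
    n_classes: int
    hyperparams: dict
    n_trainable: int

    def __post_init__(self) -> None:
        if self.arch_id not in ARCH_IDS:
            raise ValueError(f"unknown architecture {self.arch_id!r}")
        if self.n_trainable <= 0:
            raise ValueError("n_trainable must be positive")


@dataclass
class TrainConfig:
    """Optimisation settings: Adam, 15 epochs by default (up to 20 for a
    final refit of the selected configuration).

    The batch size (16) and learning rate (3e-3) suit the scaled-down
    synthetic cohorts this package trains on, where an epoch is a few dozen
    optimisation steps rather than thousands; both are overridable.
    """

    epochs: int = 15
    batch_size: int = 16
    learning_rate: float = 3e-3
    dropout_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.epochs <= 20:
            raise ValueError("epochs must be in [1, 20]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _build_network(arch_id, input_len, n_channels, n_classes, rng, hp):
    """Return (network, resolved hyperparameter dict)."""
    k = hp.get("kernel", 3)
    drop = hp.get("dropout", 0.5)
    if arch_id == "mlp":
        f = input_len * n_channels
        net = Sequential(
            [
                Flatten(),
                Dense(f, 128, rng),
                ReLU(),
                Dense(128, 64, rng),
                ReLU(),
                Dense(64, n_classes, rng),
            ]
        )
        resolved = {"hidden": (128, 64)}
    elif arch_id in ("cnn", "dilated_cnn"):
        filters = 8 if arch_id == "cnn" else 7
        hidden = 28 if arch_id == "cnn" else 42
        dil = (1, 1, 1) if arch_id == "cnn" else hp.get("dilations", (1, 2, 4))
        if input_len < 2:
            raise ValueError(f"{arch_id} needs input_len >= 2 for max pooling")
        net = Sequential(
            [
                Conv1D(n_channels, filters, k, rng, dil[0]),
                ReLU(),
                Conv1D(filters, filters, k, rng, dil[1]),
                ReLU(),
                MaxPool1D(2),
                Conv1D(filters, filters, k, rng, dil[2]),
                ReLU(),
                Dropout(drop, rng),
                GlobalAvgPool1D(),
                Dense(filters, hidden, rng),
                ReLU(),
                Dense(hidden, n_classes, rng),
            ]
        )
        resolved = {
            "filters": filters,
            "kernel": k,
            "dilations": dil,
            "hidden": hidden,
            "dropout": drop,
        }
    elif arch_id == "spatial_dropout_cnn":
        filters, kernel = 120, hp.get("kernel", 15)
        layers = []
        c = n_channels
        for d in (1, 2, 4, 8):
            layers += [
                Conv1D(c, filters, kernel, rng, d),
                ReLU(),
                SpatialDropout1D(0.05, rng),
            ]
            c = filters
        layers += [
            LSTM(filters, 256, rng),
            Dense(256, 512, rng),
            ReLU(),
            Dense(512, n_classes, rng),
        ]
        net = Sequential(layers)
        resolved = {
            "filters": filters,
            "kernel": kernel,
            "dilations": (1, 2, 4, 8),
            "spatial_dropout": 0.05,
            "lstm_units": 256,
            "hidden": 512,
        }
    elif arch_id in ("lstm_small", "lstm_large"):
        units = 4 if arch_id == "lstm_small" else 32
        layers = [
            LSTM(n_channels, units, rng, return_sequences=True),
            LSTM(units, units, rng),
            Dropout(drop, rng),
        ]
        if arch_id == "lstm_small":
            layers += [Dense(units, 64, rng), ReLU(), Dense(64, n_classes, rng)]
            resolved = {"lstm_units": units, "hidden": 64, "dropout": drop}
        else:
            layers += [Dense(units, n_classes, rng)]
            resolved = {"lstm_units": units, "dropout": drop}
        net = Sequential(layers)
    elif arch_id == "wavenet":
        rc = hp.get("residual_channels", 16)
        sc = hp.get("skip_channels", 32)
        nb = hp.get("n_blocks", 4)
        net = WaveNet(
            n_channels,
            n_classes,
            rng,
            residual_channels=rc,
            skip_channels=sc,
            kernel=hp.get("kernel", 2),
            n_blocks=nb,
        )
        resolved = {
            "residual_channels": rc,
            "skip_channels": sc,
            "kernel": hp.get("kernel", 2),
            "n_blocks": nb,
            "dilations": tuple(2**b for b in range(nb)),
        }
    elif arch_id == "conv_lstm":
        n_steps = hp.get("n_steps", 4)
        cl = ConvLSTM1x1(n_channels, 8, rng, n_steps=n_steps)
        w = input_len // cl._steps(input_len)
        net = Sequential(
            [
                cl,
                Dropout(drop, rng),
                Dense(w * 8, 64, rng),
                ReLU(),
                Dense(64, n_classes, rng),
            ]
        )
        resolved = {
            "filters": 8,
            "kernel": (1, 1),
            "stride": (1, 1),
            "n_steps": cl._steps(input_len),
            "dropout": drop,
            "hidden": 64,
        }
    else:
        raise ValueError(f"unknown architecture {arch_id!r}")
    return net, resolved


def build_model(
    arch_id: str,
    input_len: int,
    n_channels: int = 3,
    n_classes: int = 4,
    seed: int = 0,
    hyperparams: dict | None = None,
):
    """Construct one architecture; returns ``(ModelSpec, network)``."""
    if arch_id not in ARCH_IDS:
        raise ValueError(f"unknown architecture {arch_id!r}; choose from {ARCH_IDS}")
    if input_len < 1:
        raise ValueError("input_len must be >= 1")
    rng = np.random.default_rng(seed)
    net, resolved = _build_network(
        arch_id, input_len, n_channels, n_classes, rng, hyperparams or {}
    )
    spec = ModelSpec(
        arch_id=arch_id,
        input_len=input_len,
        n_channels=n_channels,
        n_classes=n_classes,
        hyperparams=resolved,
        n_trainable=net.n_params,
    )
    return spec, net


def count_parameters(model) -> int:
    """Trainable parameter count (weights + biases) of a built network or
    estimator."""
    if isinstance(model, GaitNetClassifier):
        check_is_fitted(model)
        return model.model_spec_.n_trainable
    if isinstance(model, ModelSpec):
        return model.n_trainable
    return model.n_params


class GaitNetClassifier(ClassifierMixin, BaseEstimator):
    """Window classifier wrapping the numpy architectures.

    Parameters
    ----------
    arch : str
        One of :data:`ARCH_IDS`.
    epochs, batch_size, learning_rate, dropout : training settings
        Adam at ``learning_rate``; ``dropout`` feeds the architectures'
        dropout layers (0.5 default).
    hyperparams : dict, optional
        Architecture-specific overrides (e.g. ``{"kernel": 5}``).
    random_state : int
        Seeds initialisation, dropout and batch shuffling; the same seed on
        the same data reproduces the loss curve exactly.

    The estimator accepts ``X`` of shape (n, L, 3) and string or integer
    labels.  When the labels are gait superclasses the output layer is the
    full 4-way gait vocabulary (a class missing from the training data
    triggers a warning, not an error — one reference horse never halts);
    otherwise ``classes_`` follows the data.
    """

    def __init__(
        self,
        arch: str = "conv_lstm",
        epochs: int = 15,
        batch_size: int = 16,
        learning_rate: float = 3e-3,
        dropout: float = 0.5,
        hyperparams: dict | None = None,
        random_state: int = 0,
    ):
        self.arch = arch
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.hyperparams = hyperparams
        self.random_state = random_state

    def _validate_X(self, X, fit=False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be 3-dimensional: (n_windows, length, channels)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not fit:
            check_is_fitted(self)
            if X.shape[1:] != (self.input_len_, self.n_channels_):
                raise ValueError(
                    f"window shape {X.shape[1:]} does not match the fitted "
                    f"({self.input_len_}, {self.n_channels_})"
                )
        return X

    def fit(self, X, y):
        config = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            dropout_p=self.dropout,
            seed=self.random_state,
        )
        X = self._validate_X(X, fit=True)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        present = set(np.unique(y).tolist())
        if present <= set(SUPERCLASSES):
            self.classes_ = np.array(SUPERCLASSES, dtype=object)
            missing = set(SUPERCLASSES) - present
            if missing:
                warnings.warn(
                    f"training data lacks superclass(es) {sorted(missing)}; "
                    "the model can never predict them confidently",
                    stacklevel=2,
                )
        else:
            self.classes_ = np.unique(y)
        if len(present) < 2:
            raise ValueError("need at least 2 classes present in y")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_to_idx[v] for v in y])

        self.input_len_, self.n_channels_ = X.shape[1], X.shape[2]
        rng = np.random.default_rng(self.random_state)
        hp = dict(self.hyperparams or {})
        hp.setdefault("dropout", self.dropout)
        net, resolved = _build_network(
            self.arch, self.input_len_, self.n_channels_, len(self.classes_), rng, hp
        )
        self.network_ = net
        self.model_spec_ = ModelSpec(
            arch_id=self.arch,
            input_len=self.input_len_,
            n_channels=self.n_channels_,
            n_classes=len(self.classes_),
            hyperparams=resolved,
            n_trainable=net.n_params,
        )

        opt = Adam(net.param_pairs(), lr=config.learning_rate)
        n = len(X)
        history = []
        for _ in range(config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = net.forward(X[idx], train=True)
                loss, dlogits = softmax_xent(logits, y_idx[idx])
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.history_ = history
        return self

    def predict_proba(self, X):
        X = self._validate_X(X)
        return softmax(self.network_.forward(X, train=False))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_model(
    arch_id: str,
    train: WindowedDataset,
    config: TrainConfig | None = None,
    hyperparams: dict | None = None,
) -> GaitNetClassifier:
    """Train one architecture on a (scaled) windowed dataset."""
    config = config or TrainConfig()
    clf = GaitNetClassifier(
        arch=arch_id,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        dropout=config.dropout_p,
        hyperparams=hyperparams,
        random_state=config.seed,
    )
    return clf.fit(train.X, train.y)


def predict(model: GaitNetClassifier, windows: np.ndarray):
    """Class labels and 4-way probabilities for scaled windows."""
    proba = model.predict_proba(windows)
    return model.classes_[np.argmax(proba, axis=1)], proba
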