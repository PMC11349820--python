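"""Particle-category flow and the small neural species classifier.

**Four-category flow.**  A cluster is placed in one of four behavioural
categories by crossing the presence of FFT peaks (F13-F22) with the variance
of velocity (F06) against the 0.14 threshold:

====================  ============  ===========
peaks (sum F13-F22)   F06 <= 0.14   F06 > 0.14
====================  ============  ===========
0                     Passive       Dynamic
>= 1                  Beating       Active
====================  ============  ===========

Clusters whose average velocity F01 does not exceed 0.025 pxl/ms are too
slow for the variance test to be meaningful and take the low-variance branch
(Passive/Beating by peak count); this routing is configurable.

**Species classifier.**  A fully-connected 22-20-5 network with sigmoid
activations on both layers, trained by full-batch gradient descent on the
sum-of-squared-error loss against one-hot targets.  Features are min-max
normalised to [0, 1] with bounds captured on the training set and applied
values clipped.  Prediction is the argmax of the five output activations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import ConfigError, EVPlanktonError
from .features import FeatureConfig, FeatureVector

__all__ = [
    "CategoryLabel",
    "SPECIES_LABELS",
    "classify_category",
    "normalize_features",
    "NNModel",
    "TrainConfig",
    "nn_forward",
    "nn_gradients",
    "nn_train",
    "evaluate",
]


class CategoryLabel(str, Enum):
    ACTIVE = "Active"
    DYNAMIC = "Dynamic"
    BEATING = "Beating"
    PASSIVE = "Passive"

    def __str__(self) -> str:
        return self.value


#: the five species classes of the in-vitro benchmark
SPECIES_LABELS = ("Pcra_N", "Pcra_C", "Nfus", "Ppec", "Passive")


def classify_category(
    fv: FeatureVector, config: FeatureConfig | None = None
) -> CategoryLabel:
    """Total, deterministic four-way classification of one feature vector."""
    config = (config or FeatureConfig()).validate()
    peaks = fv.peak_count
    if fv["F01"] > config.velocity_floor:
        high_var = fv["F06"] > config.f06_threshold
    else:
        high_var = False  # too slow to trust the variance test
    if peaks == 0:
        return CategoryLabel.DYNAMIC if high_var else CategoryLabel.PASSIVE
    return CategoryLabel.ACTIVE if high_var else CategoryLabel.BEATING


# ------------------------------------------------------------- normalisation


def normalize_features(train_matrix, apply_matrix=None):
    """Per-feature min-max scaling to [0, 1], fitted on the training matrix.

    Applied values are clipped to [0, 1]; constant features map to 0.
    Returns (train_scaled, apply_scaled or None, (mins, maxs)).
    """
    train = np.asarray(train_matrix, float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise EVPlanktonError("training matrix must be non-empty and 2-D")
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)

    def _apply(m):
        scaled = (np.asarray(m, float) - mins) / safe
        scaled[:, span == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    return (
        _apply(train),
        _apply(apply_matrix) if apply_matrix is not None else None,
        (mins, maxs),
    )


# ------------------------------------------------------------------- network


@dataclass
class NNModel:
    """Weights, biases and normalisation bounds of the 22-20-5 network."""

    w1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (n_out, hidden)
    b2: np.ndarray  # (n_out,)
    feature_min: np.ndarray | None = None
    feature_max: np.ndarray | None = None

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])

    @classmethod
    def init(cls, n_in=22, n_hidden=20, n_out=5, seed=0, scale=0.5) -> "NNModel":
        rng = np.random.default_rng(seed)
        return cls(
            w1=rng.uniform(-scale, scale, (n_hidden, n_in)),
            b1=rng.uniform(-scale, scale, n_hidden),
            w2=rng.uniform(-scale, scale, (n_out, n_hidden)),
            b2=rng.uniform(-scale, scale, n_out),
        )

    def normalise(self, X: np.ndarray) -> np.ndarray:
        if self.feature_min is None:
            return X
        span = self.feature_max - self.feature_min
        safe = np.where(span > 0, span, 1.0)
        scaled = (np.asarray(X, float) - self.feature_min) / safe
        scaled[:, span == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    def save(self, path) -> None:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "feature_min": None
            if self.feature_min is None
            else self.feature_min.tolist(),
            "feature_max": None
            if self.feature_max is None
            else self.feature_max.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w1=np.asarray(d["w1"]),
            b1=np.asarray(d["b1"]),
            w2=np.asarray(d["w2"]),
            b2=np.asarray(d["b2"]),
            feature_min=None
            if d["feature_min"] is None
            else np.asarray(d["feature_min"]),
            feature_max=None
            if d["feature_max"] is None
            else np.asarray(d["feature_max"]),
        )


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    epochs: int = 5000
    seed: int = 0
    init_scale: float = 0.5
    n_hidden: int = 20
    eval_every: int = 1  # record the learning curve every k epochs

    def validate(self) -> "TrainConfig":
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        return self


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def nn_forward(model: NNModel, X: np.ndarray):
    """Forward pass; returns (hidden, output) activations for rows of X."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.w1.shape[1]:
        raise EVPlanktonError(
            f"input width {X.shape[1]} != model input size {model.w1.shape[1]}"
        )
    hidden = _sigmoid(X @ model.w1.T + model.b1)
    output = _sigmoid(hidden @ model.w2.T + model.b2)
    return hidden, output


def predict(model: NNModel, X: np.ndarray) -> np.ndarray:
    """Class index per row: argmax of outputs, ties to the lowest index."""
    _, out = nn_forward(model, X)
    return out.argmax(axis=1)


def sse_loss(model: NNModel, X, Y) -> float:
    """Sum of squared error over all samples and output units."""
    _, out = nn_forward(model, X)
    return float(((out - Y) ** 2).sum())


def nn_gradients(model: NNModel, X, Y):
    """Analytic gradients of the SSE w.r.t. (w1, b1, w2, b2)."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    hidden, out = nn_forward(model, X)
    delta_out = 2.0 * (out - Y) * out * (1.0 - out)
    grad_w2 = delta_out.T @ hidden
    grad_b2 = delta_out.sum(axis=0)
    delta_hid = (delta_out @ model.w2) * hidden * (1.0 - hidden)
    grad_w1 = delta_hid.T @ X
    grad_b1 = delta_hid.sum(axis=0)
    return grad_w1, grad_b1, grad_w2, grad_b2


def nn_train(
    X_train,
    y_train,
    config: TrainConfig | None = None,
    X_test=None,
    y_test=None,
    n_classes: int | None = None,
):
    """Train the network by full-batch gradient descent on the SSE.

    ``y_train``/``y_test`` are integer class indices.  The update step uses
    the SSE gradient divided by the number of training samples so that the
    learning rate is batch-size invariant; the recorded loss is the plain
    SSE.  Returns ``(model, history)`` where history carries per-epoch
    ``loss``, ``train_acc`` and (when a test set is given) ``test_acc``.
    Deterministic given the seed.
    """
    config = (config or TrainConfig()).validate()
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, int)
    k = n_classes if n_classes is not None else int(y_train.max()) + 1
    present = np.unique(y_train)
    if len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        raise EVPlanktonError(f"classes {missing} missing from training set")
    Y = np.eye(k)[y_train]
    model = NNModel.init(
        X_train.shape[1], config.n_hidden, k, seed=config.seed,
        scale=config.init_scale,
    )
    n = X_train.shape[0]
    lr = config.learning_rate / n
    history = {"epoch": [], "loss": [], "train_acc": []}
    if X_test is not None:
        history["test_acc"] = []
    for epoch in range(config.epochs):
        gw1, gb1, gw2, gb2 = nn_gradients(model, X_train, Y)
        model.w1 -= lr * gw1
        model.b1 -= lr * gb1
        model.w2 -= lr * gw2
        model.b2 -= lr * gb2
        if epoch % config.eval_every == 0 or epoch == config.epochs - 1:
            history["epoch"].append(epoch)
            history["loss"].append(sse_loss(model, X_train, Y))
            history["train_acc"].append(
                float((predict(model, X_train) == y_train).mean())
            )
            if X_test is not None:
                history["test_acc"].append(
                    float((predict(model, X_test) == np.asarray(y_test)).mean())
                )
    for key in history:
        history[key] = np.asarray(history[key])
    return model, history


def evaluate(model: NNModel, X, y):
    """Accuracy and confusion matrix (rows = true class, cols = predicted)."""
    y = np.asarray(y, int)
    if len(y) == 0:
        raise EVPlanktonError("evaluation set is empty")
    pred = predict(model, np.asarray(X, float))
    k = model.w2.shape[0]
    confusion = np.zeros((k, k), int)
    np.add.at(confusion, (y, pred), 1)
    return float((pred == y).mean()), confusion
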