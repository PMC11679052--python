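"""Identification classifiers.

The primary model is a small fully-connected feedforward network
(Q -> 64 -> 32 -> N): ReLU after each hidden layer, dropout 0.2 during
training, softmax output, cross-entropy loss, Adam (lr 1e-3), 50 epochs of
shuffled mini-batches of 32. It is implemented directly in numpy so that the
exact recipe — including dropout and seeded batch order — is reproducible
and single-threaded deterministic.

Shallow baselines (linear SVM, KNN k=3, random forest with 100 trees, and a
gradient-boosting stand-in for XGBoost with 100 depth-2 trees at lr 0.01)
wrap scikit-learn estimators behind the same TrainedModel surface. All
models consume standardised, MI-selected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

BASELINE_KINDS = ("svm", "knn", "rf", "xgb")


@dataclass(frozen=True)
class FfnnConfig:
    """Network hyperparameters (defaults are the reference recipe)."""

    hidden_sizes: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    n_classes: int | None = None
    input_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.n_classes is not None and self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class PredictionSet:
    """Per-segment predicted labels and class-probability rows."""

    predicted_labels: np.ndarray          # (n,)
    class_probabilities: np.ndarray       # (n, N), rows sum to 1
    class_labels: np.ndarray              # (N,) label of each column


@dataclass
class TrainedModel:
    """A fitted classifier plus the label mapping it was trained with."""

    kind: str                             # ffnn | svm | knn | rf | xgb
    config: dict[str, Any]
    parameters: Any                       # _Mlp or sklearn estimator
    class_labels: np.ndarray
    input_size: int


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Mlp:
    """Minimal dense network with inverted dropout and Adam."""

    def __init__(self, sizes: list[int], seed: int, dropout: float):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = 1.0 / np.sqrt(fan_in)  # fan-in-scaled uniform init
            self.weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.biases.append(rng.uniform(-limit, limit, fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None):
        """Forward pass; rng enables dropout (training mode)."""
        acts, masks = [x], []
        h = x
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
            if rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        return acts, masks, logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        _, _, logits = self._forward(x, rng=None)
        return _softmax(logits)

    def _adam_step(self, grads: list[np.ndarray], lr: float,
                   b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        params = self.weights + self.biases
        self._adam_t += 1
        t = self._adam_t
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            mhat = self._adam_m[i] / (1 - b1 ** t)
            vhat = self._adam_v[i] / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_batch(self, x: np.ndarray, y_onehot: np.ndarray, lr: float,
                    rng: np.random.Generator) -> float:
        acts, masks, logits = self._forward(x, rng=rng)
        probs = _softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.sum(y_onehot * np.log(probs + eps)) / n
        # backprop
        delta = (probs - y_onehot) / n
        w_grads = [np.empty(0)] * len(self.weights)
        b_grads = [np.empty(0)] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            w_grads[i] = acts[i].T @ delta
            b_grads[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        self._adam_step(w_grads + b_grads, lr)
        return float(loss)


def train_ffnn(train_values: np.ndarray, labels: np.ndarray,
               config: FfnnConfig | None = None) -> TrainedModel:
    """Train the feedforward network on standardised selected features.

    Deterministic given ``config.seed`` (weight init, dropout masks and batch
    order all derive from it). Raises if a class listed in ``config.n_classes``
    has no training rows, or if the loss diverges to NaN.
    """
    config = config or FfnnConfig()
    x = np.asarray(train_values, dtype=float)
    y = np.asarray(labels)
    class_labels = np.unique(y)
    if class_labels.size < 2:
        raise ValueError("training requires at least 2 classes")
    if config.n_classes is not None and class_labels.size != config.n_classes:
        expected = set(range(1, config.n_classes + 1))
        missing = sorted(expected - set(int(c) for c in class_labels))
        raise ValueError(
            f"expected {config.n_classes} classes but only "
            f"{class_labels.size} present in training data"
            + (f"; missing labels {missing}" if missing else ""))
    if config.input_size is not None and x.shape[1] != config.input_size:
        raise ValueError(
            f"expected input size {config.input_size}, got {x.shape[1]}")

    y_idx = np.searchsorted(class_labels, y)
    onehot = np.eye(class_labels.size)[y_idx]
    sizes = [x.shape[1], *config.hidden_sizes, class_labels.size]
    net = _Mlp(sizes, seed=config.seed, dropout=config.dropout_rate)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = net.train_batch(x[idx], onehot[idx], config.learning_rate, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training aborted: loss became non-finite (check feature "
                    "standardisation and learning rate)")
    return TrainedModel(kind="ffnn", config=vars(config) | {},
                        parameters=net, class_labels=class_labels,
                        input_size=x.shape[1])


def train_baseline(kind: str, train_values: np.ndarray, labels: np.ndarray,
                   **overrides) -> TrainedModel:
    """Fit one of the benchmark classifiers with its reference defaults.

    svm: linear kernel, C = 1, one-vs-rest; knn: k = 3, Euclidean, uniform
    vote fractions as confidence; rf: 100 trees, random_state 123, full
    depth; xgb: gradient boosting with 100 trees, max depth 2, lr 0.01
    (XGBoost stand-in).
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    x = np.asarray(train_values, dtype=float)
    y = np.asarray(labels)
    if kind == "svm":
        params = {"kernel": "linear", "C": 1.0} | overrides
        est = SVC(decision_function_shape="ovr", **params)
    elif kind == "knn":
        params = {"n_neighbors": 3} | overrides
        est = KNeighborsClassifier(metric="euclidean", **params)
    elif kind == "rf":
        params = {"n_estimators": 100, "random_state": 123,
                  "max_depth": None} | overrides
        est = RandomForestClassifier(**params)
    elif kind == "xgb":
        params = {"n_estimators": 100, "max_depth": 2,
                  "learning_rate": 0.01} | overrides
        est = GradientBoostingClassifier(**params)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; "
                         f"expected one of {('ffnn',) + BASELINE_KINDS}")
    est.fit(x, y)
    return TrainedModel(kind=kind, config=params, parameters=est,
                        class_labels=np.asarray(est.classes_),
                        input_size=x.shape[1])


def predict(model: TrainedModel, values: np.ndarray) -> PredictionSet:
    """Score feature rows: class-probability rows plus their argmax labels.

    Probabilities are softmax outputs for the network, vote fractions for
    KNN/RF, softmax-normalised margins for SVM, and staged-probability
    outputs for the boosting model. The predicted label is always the argmax
    of the probability row (ties toward the smaller class index).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.input_size:
        raise ValueError(
            f"expected feature rows of dimension {model.input_size}, "
            f"got shape {x.shape}")
    if model.kind == "ffnn":
        probs = model.parameters.predict_proba(x)
    elif model.kind == "svm":
        margins = model.parameters.decision_function(x)
        if margins.ndim == 1:  # binary: build two-column margins
            margins = np.column_stack([-margins, margins])
        probs = _softmax(margins)
    else:
        probs = model.parameters.predict_proba(x)
    probs = probs / probs.sum(axis=1, keepdims=True)
    labels = model.class_labels[np.argmax(probs, axis=1)]
    return PredictionSet(predicted_labels=labels, class_probabilities=probs,
                         class_labels=model.class_labels.copy())
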