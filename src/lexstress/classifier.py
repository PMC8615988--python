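"""Binary stress-pattern classifier (SW vs WS) with confidence estimates.

A small feed-forward network (two ReLU hidden layers, softmax output) maps
the fixed-length syllable-pair vector to a stress label.  Training is
minibatch stochastic gradient descent on the cross-entropy loss with an
adaptive learning rate: the rate is halved whenever the validation loss
fails to improve for ``lr_patience`` epochs, training stops after
``early_stop_patience`` non-improving epochs, and the weights with the best
validation loss are kept.  The confidence of a call is the softmax posterior
of the predicted class; an exact 0.5/0.5 tie resolves to SW (the first
class), since ``argmax`` takes the lowest index.

The network is implemented directly on numpy so that training is exactly
reproducible from the seed (bit-identical weights across runs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .vectorize import StressVector

__all__ = [
    "CLASSES",
    "StressCall",
    "DivergenceError",
    "StressClassifier",
    "train_dnn",
    "predict_stress",
]

#: Fixed class order; index 0 (SW) wins exact posterior ties.
CLASSES = ("SW", "WS")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class StressCall:
    """A binary stress decision with its posterior probability."""

    label: str
    confidence: float


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class StressClassifier(BaseEstimator, ClassifierMixin):
    """MLP stress classifier: fit / predict / predict_proba.

    Parameters mirror the training recipe described in the module docstring;
    all are exposed for experimentation but the defaults are the ones used
    throughout the package.
    """

    def __init__(self, hidden_layer_sizes=(64, 32), batch_size: int = 32,
                 learning_rate: float = 0.01, lr_patience: int = 5,
                 early_stop_patience: int = 15, max_epochs: int = 200,
                 validation_fraction: float = 0.2,
                 random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_patience = lr_patience
        self.early_stop_patience = early_stop_patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _init_weights(self, n_in: int, rng: np.random.Generator):
        sizes = [n_in, *self.hidden_layer_sizes, 2]
        coefs, intercepts = [], []
        for a, b in zip(sizes, sizes[1:]):
            coefs.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            intercepts.append(np.zeros(b))
        return coefs, intercepts

    def _forward(self, X, coefs, intercepts):
        acts = [X]
        h = X
        for W, b in zip(coefs[:-1], intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = h @ coefs[-1] + intercepts[-1]
        return acts, logits

    def _loss(self, X, y_idx, coefs, intercepts) -> float:
        _, logits = self._forward(X, coefs, intercepts)
        p = _softmax(logits)
        return float(-np.mean(np.log(p[np.arange(len(y_idx)), y_idx] + 1e-12)))

    # -- API ----------------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on labelled vectors; ``validation_data=(X_val, y_val)``
        overrides the internal seeded split."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        labels = set(np.unique(y))
        if not labels <= set(CLASSES):
            raise ValueError(f"labels must be in {CLASSES}, got {sorted(labels)}")
        if len(labels) < 2:
            raise ValueError("training set must contain both SW and WS")
        y_idx = np.array([CLASSES.index(lab) for lab in y])
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            Xv = np.asarray(validation_data[0], dtype=np.float64)
            yv_idx = np.array([CLASSES.index(lab) for lab in validation_data[1]])
            Xt, yt = X, y_idx
        else:
            perm = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val, tr = perm[:n_val], perm[n_val:]
            Xt, yt, Xv, yv_idx = X[tr], y_idx[tr], X[val], y_idx[val]

        coefs, intercepts = self._init_weights(X.shape[1], rng)
        lr = self.learning_rate
        best_loss = np.inf
        best = None
        since_improve = 0
        train_curve, val_curve = [], []
        for _epoch in range(self.max_epochs):
            order = rng.permutation(len(Xt))
            for start in range(0, len(Xt), self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = Xt[batch], yt[batch]
                acts, logits = self._forward(xb, coefs, intercepts)
                p = _softmax(logits)
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad /= len(yb)
                for layer in range(len(coefs) - 1, -1, -1):
                    a = acts[layer]
                    gW = a.T @ grad
                    gb = grad.sum(axis=0)
                    if layer > 0:
                        grad = (grad @ coefs[layer].T) * (acts[layer] > 0)
                    coefs[layer] -= lr * gW
                    intercepts[layer] -= lr * gb
            tr_loss = self._loss(Xt, yt, coefs, intercepts)
            va_loss = self._loss(Xv, yv_idx, coefs, intercepts)
            if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
                raise DivergenceError(
                    f"non-finite loss at learning rate {lr:g}"
                )
            train_curve.append(tr_loss)
            val_curve.append(va_loss)
            if va_loss < best_loss - 1e-9:
                best_loss = va_loss
                best = ([W.copy() for W in coefs], [b.copy() for b in intercepts])
                since_improve = 0
            else:
                since_improve += 1
                if since_improve % self.lr_patience == 0:
                    lr *= 0.5
                if since_improve >= self.early_stop_patience:
                    break
        self.coefs_, self.intercepts_ = best
        self.classes_ = np.array(CLASSES)
        self.n_features_in_ = X.shape[1]
        self.best_validation_loss_ = best_loss
        self.train_loss_curve_ = np.array(train_curve)
        self.validation_loss_curve_ = np.array(val_curve)
        self.final_learning_rate_ = lr
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected vectors of length {self.n_features_in_}, "
                f"got {X.shape[1]}"
            )
        _, logits = self._forward(X, self.coefs_, self.intercepts_)
        return _softmax(logits)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def call(self, vector) -> StressCall:
        """Single-vector prediction as a StressCall."""
        values = vector.values if isinstance(vector, StressVector) else vector
        p = self.predict_proba(values)[0]
        k = int(np.argmax(p))  # tie (0.5, 0.5) -> index 0 = SW
        return StressCall(CLASSES[k], float(p[k]))

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "params": self.get_params(),
            "coefs": [W.tolist() for W in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "n_features_in": int(self.n_features_in_),
            "best_validation_loss": float(self.best_validation_loss_),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StressClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        params = doc["params"]
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        est = cls(**params)
        est.coefs_ = [np.array(W) for W in doc["coefs"]]
        est.intercepts_ = [np.array(b) for b in doc["intercepts"]]
        est.classes_ = np.array(CLASSES)
        est.n_features_in_ = doc["n_features_in"]
        est.best_validation_loss_ = doc["best_validation_loss"]
        return est


def train_dnn(train, train_labels, valid, valid_labels,
              seed: int | None = None, **hyper) -> StressClassifier:
    """Train the stress classifier on explicit train/validation splits."""
    est = StressClassifier(random_state=seed, **hyper)
    X = np.vstack([v.values if isinstance(v, StressVector) else v for v in train])
    Xv = np.vstack([v.values if isinstance(v, StressVector) else v for v in valid])
    return est.fit(X, train_labels, validation_data=(Xv, valid_labels))


def predict_stress(model: StressClassifier, vector) -> StressCall:
    """Classify one syllable-pair vector."""
    return model.call(vector)
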