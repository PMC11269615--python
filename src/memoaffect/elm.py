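"""Extreme Learning Machine classifier.

A single hidden layer whose input weights and biases are drawn at random and
never trained; the output weights are the minimum-norm least-squares solution
beta = pinv(H) @ T, where H = act(X W^T + b) is the hidden-layer response and
T the one-hot targets.  With the replication default of 9000 hidden neurons
and 32-dimensional input features, H is rank-limited by the feature
dimension; the SVD-based pseudoinverse handles this without regularization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crnn import _sigmoid


@dataclass
class ELMModel:
    """Random fixed hidden layer plus least-squares output weights."""

    input_weights: np.ndarray   # L x d
    hidden_biases: np.ndarray   # L
    output_weights: np.ndarray  # L x n_classes
    classes: np.ndarray
    hidden_activation: str = "sigmoid"
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            input_weights=self.input_weights,
            hidden_biases=self.hidden_biases,
            output_weights=self.output_weights,
            classes=self.classes,
            hidden_activation=np.array(self.hidden_activation),
            seed=np.array(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ELMModel":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                input_weights=z["input_weights"],
                hidden_biases=z["hidden_biases"],
                output_weights=z["output_weights"],
                classes=z["classes"],
                hidden_activation=str(z["hidden_activation"]),
                seed=None if seed < 0 else seed,
            )


def _hidden(model_or_W, biases, X, kind: str) -> np.ndarray:
    H = X @ model_or_W.T + biases
    if kind == "sigmoid":
        return _sigmoid(H)
    if kind == "tanh":
        return np.tanh(H)
    if kind == "relu":
        return np.maximum(0, H)
    raise ValueError(f"unknown hidden activation {kind!r}")


def elm_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 9000,
    rng: np.random.Generator | int | None = None,
    hidden_activation: str = "sigmoid",
) -> ELMModel:
    """Fit an ELM: random hidden layer, closed-form output weights.

    Input weights are uniform on [-1, 1], biases uniform on [0, 1]; the
    output weights solve min ||H beta - T||_2 via the SVD pseudoinverse.
    """
    X = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = np.asarray(labels)
    classes = np.unique(y)
    if X.shape[0] < classes.size:
        raise ValueError("need at least one sample per class")
    seed = rng if isinstance(rng, int) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    d = X.shape[1]
    W = gen.uniform(-1.0, 1.0, size=(n_hidden, d))
    b = gen.uniform(0.0, 1.0, size=n_hidden)
    H = _hidden(W, b, X, hidden_activation)
    T = (y[:, None] == classes[None, :]).astype(np.float64)
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return ELMModel(
        input_weights=W,
        hidden_biases=b,
        output_weights=beta,
        classes=classes,
        hidden_activation=hidden_activation,
        seed=seed,
    )


def elm_predict(model: ELMModel, features: np.ndarray):
    """Class labels and raw scores; ties break to the lowest class index."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != model.input_weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the fitted model "
            f"({model.input_weights.shape[1]})"
        )
    H = _hidden(model.input_weights, model.hidden_biases, X, model.hidden_activation)
    scores = H @ model.output_weights
    labels = model.classes[scores.argmax(axis=1)]
    return labels, scores


def internal_split(
    features: np.ndarray,
    labels: np.ndarray,
    validation_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
):
    """Stratified random split of the training pool into train/validation.

    The validation side exists for reporting only (no tuning loop).  If a
    class is missing from either side the split is re-drawn once, then an
    error is raised.
    """
    from sklearn.model_selection import train_test_split

    X = np.asarray(features)
    y = np.asarray(labels)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 samples to split")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    classes = np.unique(y)
    for attempt in range(2):
        seed = int(gen.integers(0, 2**31 - 1))
        try:
            Xtr, Xva, ytr, yva = train_test_split(
                X, y, test_size=validation_fraction, random_state=seed, stratify=y
            )
        except ValueError:
            Xtr, Xva, ytr, yva = train_test_split(
                X, y, test_size=validation_fraction, random_state=seed
            )
        if set(np.unique(ytr)) == set(classes) and set(np.unique(yva)) == set(classes):
            return (Xtr, ytr), (Xva, yva)
    raise ValueError("a class is absent from one side of the split after re-draw")
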