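"""Extreme learning machine: a single-hidden-layer feed-forward network.

Input weights ``a`` (G x n) and biases ``c`` (G,) are fixed at random (or
supplied by an optimizer); only the output weights ``w`` (G x m) are
learned, in closed form, as the minimum-norm least-squares solution
``w = pinv(M) @ T`` where ``M[j, i] = f(a_i . x_j + c_i)`` is the hidden
layer output matrix.  With as many hidden nodes as distinct samples the
network interpolates its training set exactly (up to floating point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ELMModel",
    "TargetEncoding",
    "one_hot_targets",
    "hidden_matrix",
    "train",
    "predict",
    "predict_labels",
    "mean_squared_error",
    "save_model",
    "load_model",
]

_ACTIVATIONS = {
    "sigmoid": expit,
    "linear": lambda z: z,
    "tanh": np.tanh,
}

# relative singular-value cutoff for the Moore-Penrose pseudoinverse
_PINV_RCOND = 1e-10


@dataclass
class ELMModel:
    """Trained single-hidden-layer network."""

    input_weights: np.ndarray  # (G, n)
    biases: np.ndarray  # (G,)
    output_weights: np.ndarray  # (G, m)
    activation: str = "sigmoid"
    class_labels: np.ndarray | None = None  # set for one-hot classification

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.output_weights.shape[1]


@dataclass
class TargetEncoding:
    """One-hot target matrix with its label ordering."""

    matrix: np.ndarray  # (H, m), rows one-hot
    class_labels: np.ndarray  # (m,)


def one_hot_targets(labels: Sequence[int] | np.ndarray) -> TargetEncoding:
    """Encode integer labels as one-hot rows, classes in sorted order."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    matrix = (labels[:, None] == classes[None, :]).astype(float)
    return TargetEncoding(matrix=matrix, class_labels=classes)


def hidden_matrix(
    X: np.ndarray,
    input_weights: np.ndarray,
    biases: np.ndarray,
    activation: str = "sigmoid",
) -> np.ndarray:
    """Hidden-layer output M with M[j, i] = f(a_i . x_j + c_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    input_weights = np.asarray(input_weights, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if X.shape[1] != input_weights.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[1]} columns, "
            f"weights expect {input_weights.shape[1]}"
        )
    if biases.shape != (input_weights.shape[0],):
        raise ValueError("bias vector length must equal hidden-node count")
    try:
        f = _ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None
    return f(X @ input_weights.T + biases)


def train(
    X: np.ndarray,
    targets: TargetEncoding | np.ndarray,
    n_hidden: int,
    activation: str = "sigmoid",
    rng: np.random.Generator | int | None = None,
    input_weights: np.ndarray | None = None,
    biases: np.ndarray | None = None,
) -> ELMModel:
    """Fit output weights by pseudoinverse for given/random input weights.

    Input weights and biases are drawn uniformly in [-1, 1] unless supplied
    explicitly (e.g. by the KCBGWO tuner).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.isnan(X).any():
        raise ValueError("training features contain NaN")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    class_labels = None
    if isinstance(targets, TargetEncoding):
        class_labels = targets.class_labels
        T = targets.matrix
    else:
        T = np.asarray(targets, dtype=float)
        if T.ndim == 1:
            T = T[:, None]
    if T.shape[0] != X.shape[0]:
        raise ValueError("sample count mismatch between X and targets")

    n = X.shape[1]
    if input_weights is None or biases is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if input_weights is None:
            input_weights = rng.uniform(-1.0, 1.0, size=(n_hidden, n))
        if biases is None:
            biases = rng.uniform(-1.0, 1.0, size=n_hidden)
    input_weights = np.asarray(input_weights, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if input_weights.shape != (n_hidden, n):
        raise ValueError(
            f"input_weights must be ({n_hidden}, {n}), got {input_weights.shape}"
        )

    M = hidden_matrix(X, input_weights, biases, activation)
    output_weights = np.linalg.pinv(M, rcond=_PINV_RCOND) @ T
    return ELMModel(
        input_weights=input_weights,
        biases=biases,
        output_weights=output_weights,
        activation=activation,
        class_labels=class_labels,
    )


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Network outputs g(x) = f(a x + c) w for each row of X."""
    M = hidden_matrix(X, model.input_weights, model.biases, model.activation)
    return M @ model.output_weights


def predict_labels(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Class decisions by row-wise arg-max over the output columns."""
    if model.class_labels is None:
        raise ValueError("model was not trained with a one-hot TargetEncoding")
    scores = predict(model, X)
    return model.class_labels[np.argmax(scores, axis=1)]


def mean_squared_error(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean over all entries of the squared differences."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: {observed.shape} vs {predicted.shape}"
        )
    return float(np.mean((observed - predicted) ** 2))


def save_model(model: ELMModel, path: str | Path) -> None:
    """Serialize a model to JSON (plain nested arrays)."""
    payload = {
        "input_weights": model.input_weights.tolist(),
        "biases": model.biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "activation": model.activation,
        "class_labels": None
        if model.class_labels is None
        else np.asarray(model.class_labels).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ELMModel:
    payload = json.loads(Path(path).read_text())
    labels = payload["class_labels"]
    return ELMModel(
        input_weights=np.asarray(payload["input_weights"], dtype=float),
        biases=np.asarray(payload["biases"], dtype=float),
        output_weights=np.asarray(payload["output_weights"], dtype=float),
        activation=payload["activation"],
        class_labels=None if labels is None else np.asarray(labels),
    )
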