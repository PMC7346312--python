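"""Backpropagation multilayer perceptron trained by gradient descent on
squared error.

Deliberately minimal: sigmoid units throughout, a single output unit with a
0.5 decision threshold, full-batch gradient descent (deterministic for a
fixed seed), weights initialized uniformly in [-0.5, 0.5].  No momentum,
regularization or early stopping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DivergenceError, ParameterError

logger = logging.getLogger(__name__)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPModel:
    layer_sizes: list[int]  # [d, h1, ..., 1]
    weights: list[np.ndarray]  # W[l] has shape (out, in)
    biases: list[np.ndarray]
    rng_seed: int = 0
    loss_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (self.layer_sizes[l + 1], self.layer_sizes[l]):
                raise ParameterError(f"weight shape mismatch at layer {l}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ParameterError(f"bias shape mismatch at layer {l}")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ParameterError(f"non-finite parameters at layer {l}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "layer_sizes": self.layer_sizes,
                    "weights": [W.tolist() for W in self.weights],
                    "biases": [b.tolist() for b in self.biases],
                    "rng_seed": self.rng_seed,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            layer_sizes=list(obj["layer_sizes"]),
            weights=[np.array(W, dtype=float) for W in obj["weights"]],
            biases=[np.array(b, dtype=float) for b in obj["biases"]],
            rng_seed=int(obj["rng_seed"]),
        )


def init_mlp(d: int, hidden: list[int], seed: int = 0) -> MLPModel:
    sizes = [d, *hidden, 1]
    rng = np.random.default_rng(seed)
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l]))
        for l in range(len(sizes) - 1)
    ]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[l + 1]) for l in range(len(sizes) - 1)]
    return MLPModel(layer_sizes=sizes, weights=weights, biases=biases, rng_seed=seed)


def _forward(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input included; X is (n, d)."""
    acts = [X]
    a = X
    for W, b in zip(model.weights, model.biases):
        a = _sigmoid(a @ W.T + b)
        acts.append(a)
    return acts


def loss_and_gradients(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean squared error and its analytic gradients w.r.t. every parameter."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n = X.shape[0]
    acts = _forward(model, X)
    out = acts[-1]
    loss = float(np.mean((out - y) ** 2))

    grad_W: list[np.ndarray] = [np.empty(0)] * len(model.weights)
    grad_b: list[np.ndarray] = [np.empty(0)] * len(model.biases)
    # delta at layer l = dL/dz_l with z the pre-activation
    delta = (2.0 / n) * (out - y) * out * (1.0 - out)
    for l in range(len(model.weights) - 1, -1, -1):
        grad_W[l] = delta.T @ acts[l]
        grad_b[l] = delta.sum(axis=0)
        if l > 0:
            a = acts[l]
            delta = (delta @ model.weights[l]) * a * (1.0 - a)
    return loss, grad_W, grad_b


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden: list[int] | None = None,
    lr: float = 0.5,
    epochs: int = 1000,
    seed: int = 0,
) -> MLPModel:
    """Full-batch gradient descent on mean squared error.

    A single-class training set is accepted with a warning (the net simply
    converges to a constant output); a NaN/inf loss raises a divergence
    error suggesting a smaller learning rate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ParameterError("empty training set")
    if X.shape[0] != y.size:
        raise ParameterError("X and y disagree on the number of samples")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ParameterError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        logger.warning(
            "single-class training set (all labels %g); net will predict a constant",
            y[0] if y.size else float("nan"),
        )
        warnings.warn("training on a single-class subset", stacklevel=2)

    d = X.shape[1]
    if hidden is None:
        hidden = [max(8, int(round(np.sqrt(d))))]
    model = init_mlp(d, list(hidden), seed=seed)

    for _ in range(epochs):
        loss, gW, gb = loss_and_gradients(model, X, y)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"loss diverged to {loss}; try a smaller learning rate than {lr}"
            )
        model.loss_trajectory.append(loss)
        for l in range(len(model.weights)):
            model.weights[l] -= lr * gW[l]
            model.biases[l] -= lr * gb[l]
    return model


def predict(model: MLPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, hard labels); label 1 iff output >= 0.5."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ParameterError(
            f"feature dimension {X.shape[1]} does not match model input "
            f"{model.layer_sizes[0]}"
        )
    probs = _forward(model, X)[-1].ravel()
    return probs, (probs >= 0.5).astype(int)
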