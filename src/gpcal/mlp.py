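"""Densely connected feed-forward network for single-trait regression.

Architecture: equal-width ReLU hidden layers with inverted dropout after
each, a single linear output unit, mean-squared-error loss, and Adam
updates. The tuning grid is the fixed eight-point Cartesian product of
two hidden widths (1.5x and 3x the number of input variables), one or
four hidden layers, and dropout 0.15 or 0.30, all at learning rate 0.001
for 1,000 epochs.

The implementation is a compact, fully seeded numpy network: inputs and
the response are standardized by training statistics (predictions are
returned on the original trait scale), weights use Glorot-uniform
initialization, and dropout masks come from the same generator as the
batch shuffling, so a (data, seed) pair maps to bit-identical models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["HyperParams", "MLPModel", "hyperparameter_grid", "train_mlp",
           "predict_mlp"]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass(frozen=True)
class HyperParams:
    """One point of the tuning grid."""

    units_multiplier: float
    n_hidden_layers: int
    dropout: float
    learning_rate: float = 0.001
    epochs: int = 1000

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.units_multiplier <= 0:
            raise ValueError("units_multiplier must be > 0")


def hyperparameter_grid(n_inputs: int) -> list[HyperParams]:
    """The fixed eight-configuration grid, in a stable documented order.

    Order is multiplier-major, then hidden-layer count, then dropout
    (dropout varies fastest); selection ties downstream break toward the
    earliest entry, so this order is part of the contract.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    return [
        HyperParams(units_multiplier=m, n_hidden_layers=h, dropout=d)
        for m, h, d in itertools.product((1.5, 3.0), (1, 4), (0.15, 0.30))
    ]


def _hidden_width(hp: HyperParams, n_inputs: int) -> int:
    # round half-up, floored at one unit
    return max(1, int(math.floor(hp.units_multiplier * n_inputs + 0.5)))


@dataclass
class MLPModel:
    """Trained network plus the standardization needed to use it."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hp: HyperParams
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    seed: int

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_mlp(self, X)


def _forward_train(Xb, weights, biases, dropout, rng):
    """Forward pass with inverted dropout; returns activations and masks."""
    acts = [Xb]
    masks = []
    a = Xb
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(a @ W + b, 0.0)
        if dropout > 0.0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        else:
            mask = None
        masks.append(mask)
        acts.append(h)
        a = h
    out = a @ weights[-1] + biases[-1]
    return acts, masks, out


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    seed: int,
    batch_size: int = 32,
) -> MLPModel:
    """Train the network for exactly ``hp.epochs`` epochs.

    Inputs and response are standardized by training means/SDs
    (zero-variance columns are centered only). Deterministic given
    ``seed``: the one generator drives initialization, epoch shuffling
    and dropout masks, in that order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if n != len(y):
        raise ValueError("X rows and y length differ")
    if n < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    width = _hidden_width(hp, p)
    sizes = [p] + [width] * hp.n_hidden_layers + [1]
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    t = 0
    lr = hp.learning_rate

    for _ in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb = Xs[idx], ys[idx]
            acts, masks, out = _forward_train(Xb, weights, biases,
                                              hp.dropout, rng)
            # MSE loss gradient
            delta = 2.0 * (out.ravel() - yb)[:, None] / len(idx)
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            grads_w[-1] = acts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            back = delta @ weights[-1].T
            for l in range(len(weights) - 2, -1, -1):
                if masks[l] is not None:
                    back = back * masks[l]
                back = back * (acts[l + 1] > 0.0)
                grads_w[l] = acts[l].T @ back
                grads_b[l] = back.sum(axis=0)
                if l > 0:
                    back = back @ weights[l].T
            t += 1
            corr = np.sqrt(1.0 - _ADAM_B2**t) / (1.0 - _ADAM_B1**t)
            for l in range(len(weights)):
                m_w[l] = _ADAM_B1 * m_w[l] + (1 - _ADAM_B1) * grads_w[l]
                v_w[l] = _ADAM_B2 * v_w[l] + (1 - _ADAM_B2) * grads_w[l] ** 2
                weights[l] -= lr * corr * m_w[l] / (np.sqrt(v_w[l]) + _ADAM_EPS)
                m_b[l] = _ADAM_B1 * m_b[l] + (1 - _ADAM_B1) * grads_b[l]
                v_b[l] = _ADAM_B2 * v_b[l] + (1 - _ADAM_B2) * grads_b[l] ** 2
                biases[l] -= lr * corr * m_b[l] / (np.sqrt(v_b[l]) + _ADAM_EPS)

    return MLPModel(
        weights=weights, biases=biases, hp=hp,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        seed=seed,
    )


def predict_mlp(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Forward pass with dropout disabled, de-standardized to trait scale."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns; model expects {model.n_inputs}"
        )
    a = (X - model.x_mean) / model.x_scale
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.maximum(a @ W + b, 0.0)
    out = (a @ model.weights[-1] + model.biases[-1]).ravel()
    return out * model.y_scale + model.y_mean
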