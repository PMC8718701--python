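"""Pluggable base learners for the evaluation protocols.

A *learner* is any callable ``learner(X, y, hp, seed) -> model`` whose
returned model exposes ``predict(X)``. The protocols default to the MLP
trainer; the alternatives here are cheap linear learners used for fast
protocol-level experiments and diagnostics:

- :class:`RidgeLearner` — closed-form ridge regression with intercept.
- :class:`AffineBiasedLearner` — a synthetic diagnostic wrapper that
  distorts another learner's predictions by a fixed affine map. It
  emulates a systematically mis-scaled predictor (the failure mode that
  output calibration is designed to repair) and exists for controlled
  experiments, not for real prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlp import HyperParams, train_mlp

__all__ = ["mlp_learner", "RidgeLearner", "AffineBiasedLearner"]


def mlp_learner(X: np.ndarray, y: np.ndarray, hp: HyperParams, seed: int):
    """Default learner: the seeded numpy MLP."""
    return train_mlp(X, y, hp, seed)


@dataclass
class _LinearModel:
    coef: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef + self.intercept


@dataclass
class RidgeLearner:
    """Closed-form ridge regression (unpenalized intercept); ignores hp."""

    alpha: float = 1.0

    def __call__(self, X, y, hp=None, seed=None) -> _LinearModel:
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xc = X - x_mean
        A = Xc.T @ Xc + self.alpha * np.eye(X.shape[1])
        coef = np.linalg.solve(A, Xc.T @ (y - y_mean))
        return _LinearModel(coef=coef, intercept=float(y_mean - x_mean @ coef))


@dataclass
class _BiasedModel:
    base: object
    slope: float
    offset: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.slope * self.base.predict(X) + self.offset


@dataclass
class AffineBiasedLearner:
    """Synthetic wrapper applying y_hat -> slope * y_hat + offset.

    Used to study calibration: the distortion is invertible by an OLS
    line of observed on predicted values, so a calibrated protocol should
    undo it while an uncalibrated one pays the full squared-bias cost.
    """

    base: object
    slope: float = 0.6
    offset: float = 1.0

    def __call__(self, X, y, hp=None, seed=None) -> _BiasedModel:
        model = self.base(X, y, hp, seed)
        return _BiasedModel(base=model, slope=self.slope, offset=self.offset)
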