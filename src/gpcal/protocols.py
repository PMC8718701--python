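"""Evaluation protocols: GBLUP cross-validation, conventional deep
learning (DL_M1) and the calibrated protocol (DL_M2).

All three share record-level 5-fold outer cross-validation: records (not
lines) are dealt into folds, so a line held out in one environment is
typically still observed in others — the "sparse trial" prediction
problem rather than new-line prediction.

DL_M1 (conventional): within each outer fold, split training 80/20 into
inner-training and validation; train every grid configuration on
inner-training, pick the validation-MSE minimizer, refit it on the full
training set (80% of all records), predict the test fold.

DL_M2 (calibrated): tune one level deeper (inner-training split 80/20
into inner-inner-training and inner-validation), refit the winner on
inner-training (64% of all records), predict both the validation slice
and the test fold, fit an ordinary-least-squares line of observed
validation values on predicted validation values, and apply that line to
the raw test predictions. The calibration line is the protocol's whole
point: it repairs affine bias (scale compression, offset) in the
network's outputs at the cost of training the final model on less data.

Fold-level mean squared errors are averaged across folds (never pooled
across records first) to report performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import PhenotypeTable
from .design import DesignSet
from .gblup import fit_gblup, predict_gblup
from .learners import mlp_learner
from .mlp import HyperParams, hyperparameter_grid

__all__ = [
    "SplitPlan",
    "FoldSplit",
    "CalibrationLine",
    "FoldOutcome",
    "ProtocolResult",
    "make_split_plan",
    "fit_calibration_line",
    "apply_calibration",
    "run_dl_m1",
    "run_dl_m2",
    "run_gblup_cv",
]

logger = logging.getLogger(__name__)


class DegenerateCalibrationError(ValueError):
    """Predicted values are constant: the calibration slope is undefined."""


@dataclass
class FoldSplit:
    """Index sets of one outer fold (all indices into the record table)."""

    test: np.ndarray                     # 20%
    train: np.ndarray                    # 80% = inner_train + validation
    inner_train: np.ndarray              # 64%
    validation: np.ndarray               # 16%
    inner_inner_train: np.ndarray | None = None   # 51.2% (nested plans)
    inner_validation: np.ndarray | None = None    # 12.8% (nested plans)


@dataclass
class SplitPlan:
    folds: list[FoldSplit]
    n_records: int
    k: int
    seed: int
    nested: bool


def _split_80_20(idx: np.ndarray, rng: np.random.Generator):
    shuffled = rng.permutation(idx)
    cut = int(np.floor(0.8 * len(shuffled)))
    return np.sort(shuffled[:cut]), np.sort(shuffled[cut:])


def make_split_plan(
    pheno: PhenotypeTable, k: int = 5, seed: int = 0, nested: bool = False
) -> SplitPlan:
    """Deal records into k outer folds with 80/20 tuning splits.

    Records are shuffled by ``seed`` and dealt into k folds whose sizes
    differ by at most one. Within each outer fold the training records
    are split 80/20 into inner-training and validation; if ``nested``,
    inner-training is split 80/20 again into inner-inner-training and
    inner-validation (the extra level DL_M2 needs).
    """
    n = pheno.n_records
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds record count {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(n)
    fold_tests = np.array_split(order, k)
    folds = []
    for test in fold_tests:
        test = np.sort(test)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test] = False
        train = np.flatnonzero(train_mask)
        inner_train, validation = _split_80_20(train, rng)
        iit = ival = None
        if nested:
            iit, ival = _split_80_20(inner_train, rng)
        folds.append(
            FoldSplit(test=test, train=train, inner_train=inner_train,
                      validation=validation, inner_inner_train=iit,
                      inner_validation=ival)
        )
    return SplitPlan(folds=folds, n_records=n, k=k, seed=seed, nested=nested)


@dataclass
class CalibrationLine:
    """OLS intercept/slope mapping raw predictions to adjusted ones."""

    intercept: float
    slope: float
    n_points: int
    mse_before: float
    mse_after: float


def fit_calibration_line(
    observed: np.ndarray, predicted: np.ndarray
) -> CalibrationLine:
    """OLS of observed on predicted values, by the closed-form normal
    equations.

    Minimizes sum (observed - b0 - b1 * predicted)^2. Raises
    :class:`DegenerateCalibrationError` when the predictions carry no
    variance (undefined slope).
    """
    obs = np.asarray(observed, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    if len(obs) < 2:
        raise ValueError("need at least 2 points to fit a line")
    pbar, obar = pred.mean(), obs.mean()
    sxx = float(np.sum((pred - pbar) ** 2))
    if sxx == 0.0:
        raise DegenerateCalibrationError("constant predictions")
    slope = float(np.sum((pred - pbar) * (obs - obar)) / sxx)
    intercept = float(obar - slope * pbar)
    before = float(np.mean((obs - pred) ** 2))
    after = float(np.mean((obs - intercept - slope * pred) ** 2))
    return CalibrationLine(intercept=intercept, slope=slope,
                           n_points=len(obs), mse_before=before,
                           mse_after=after)


def apply_calibration(line: CalibrationLine, predictions: np.ndarray) -> np.ndarray:
    """Adjusted predictions b0 + b1 * p, elementwise."""
    return line.intercept + line.slope * np.asarray(predictions, float)


@dataclass
class FoldOutcome:
    fold: int
    test_idx: np.ndarray
    predictions: np.ndarray
    mse: float
    per_env_mse: dict[str, float]
    chosen_hp: HyperParams | None = None
    calibration: CalibrationLine | None = None
    n_train_final: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class ProtocolResult:
    """Out-of-fold predictions and fold-level errors for one method."""

    method: str
    folds: list[FoldOutcome]
    oof_predictions: np.ndarray
    env_of_record: np.ndarray
    plan_seed: int
    k: int

    @property
    def fold_mses(self) -> np.ndarray:
        return np.array([f.mse for f in self.folds])

    def mean_mse(self) -> float:
        """Average of the k fold-level MSEs (fold-then-mean)."""
        return float(self.fold_mses.mean())

    def per_env_mean_mse(self) -> dict[str, float]:
        envs: dict[str, list[float]] = {}
        for f in self.folds:
            for e, v in f.per_env_mse.items():
                envs.setdefault(e, []).append(v)
        return {e: float(np.mean(v)) for e, v in envs.items()}


def _seed_for(master: int, *key: int) -> int:
    """Deterministic child seed < 2^31 for a (fold, stage, ...) key."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _per_env_mse(y, yhat, envs):
    out = {}
    for e in np.unique(envs):
        m = envs == e
        out[str(e)] = float(np.mean((y[m] - yhat[m]) ** 2))
    return out


def _grid_search(X, y, grid, train_idx, score_idx, learner, master_seed, fold):
    """Train every configuration; return (best hp, its index) by score MSE.

    Ties break toward the earliest grid entry.
    """
    best_hp, best_mse, best_i = None, np.inf, -1
    for i, hp in enumerate(grid):
        model = learner(X[train_idx], y[train_idx], hp,
                        _seed_for(master_seed, fold, 1, i))
        m = float(np.mean((y[score_idx] - model.predict(X[score_idx])) ** 2))
        logger.debug("fold %d grid[%d] %s -> MSE %.5f", fold, i, hp, m)
        if m < best_mse:
            best_hp, best_mse, best_i = hp, m, i
    return best_hp, best_i


def run_dl_m1(
    pheno: PhenotypeTable,
    design: DesignSet,
    plan: SplitPlan,
    seed: int,
    learner=mlp_learner,
    grid: list[HyperParams] | None = None,
) -> ProtocolResult:
    """Conventional protocol: tune on 80/20, refit winner on all training.

    ``learner`` may be any ``(X, y, hp, seed) -> model`` callable; the
    default is the MLP trainer. ``grid`` defaults to the eight-point
    hyperparameter grid for the design's predictor width.
    """
    X = design.matrix()
    y = pheno.y
    if grid is None:
        grid = hyperparameter_grid(X.shape[1])
    oof = np.full(len(y), np.nan)
    outcomes = []
    for f, fold in enumerate(plan.folds):
        hp, _ = _grid_search(X, y, grid, fold.inner_train, fold.validation,
                             learner, seed, f)
        final = learner(X[fold.train], y[fold.train], hp,
                        _seed_for(seed, f, 2))
        yhat = final.predict(X[fold.test])
        oof[fold.test] = yhat
        outcomes.append(FoldOutcome(
            fold=f, test_idx=fold.test, predictions=yhat,
            mse=float(np.mean((y[fold.test] - yhat) ** 2)),
            per_env_mse=_per_env_mse(y[fold.test], yhat,
                                     pheno.record_envs[fold.test]),
            chosen_hp=hp, n_train_final=len(fold.train),
        ))
    return ProtocolResult(method="dl_m1", folds=outcomes, oof_predictions=oof,
                          env_of_record=pheno.record_envs,
                          plan_seed=plan.seed, k=plan.k)


def run_dl_m2(
    pheno: PhenotypeTable,
    design: DesignSet,
    plan: SplitPlan,
    seed: int,
    learner=mlp_learner,
    grid: list[HyperParams] | None = None,
) -> ProtocolResult:
    """Calibrated protocol: nested tuning, then an OLS output calibration.

    Per fold: grid-search on inner-inner-training scored on
    inner-validation; refit the winner on inner-training; predict the
    validation slice and the test fold; fit the calibration line
    (observed validation ~ predicted validation) and apply it to the test
    predictions. If the validation predictions are constant the line is
    undefined and an identity line is used with a warning.
    """
    if not plan.nested:
        raise ValueError("run_dl_m2 needs a nested split plan")
    X = design.matrix()
    y = pheno.y
    if grid is None:
        grid = hyperparameter_grid(X.shape[1])
    oof = np.full(len(y), np.nan)
    outcomes = []
    for f, fold in enumerate(plan.folds):
        hp, _ = _grid_search(X, y, grid, fold.inner_inner_train,
                             fold.inner_validation, learner, seed, f)
        final = learner(X[fold.inner_train], y[fold.inner_train], hp,
                        _seed_for(seed, f, 2))
        pred_val = final.predict(X[fold.validation])
        pred_test = final.predict(X[fold.test])
        try:
            line = fit_calibration_line(y[fold.validation], pred_val)
        except DegenerateCalibrationError:
            logger.warning(
                "fold %d: constant validation predictions; using identity "
                "calibration", f)
            before = float(np.mean((y[fold.validation] - pred_val) ** 2))
            line = CalibrationLine(intercept=0.0, slope=1.0,
                                   n_points=len(pred_val),
                                   mse_before=before, mse_after=before)
        yhat = apply_calibration(line, pred_test)
        oof[fold.test] = yhat
        outcomes.append(FoldOutcome(
            fold=f, test_idx=fold.test, predictions=yhat,
            mse=float(np.mean((y[fold.test] - yhat) ** 2)),
            per_env_mse=_per_env_mse(y[fold.test], yhat,
                                     pheno.record_envs[fold.test]),
            chosen_hp=hp, calibration=line,
            n_train_final=len(fold.inner_train),
            extras={"uncalibrated_test_mse":
                    float(np.mean((y[fold.test] - pred_test) ** 2))},
        ))
    return ProtocolResult(method="dl_m2", folds=outcomes, oof_predictions=oof,
                          env_of_record=pheno.record_envs,
                          plan_seed=plan.seed, k=plan.k)


def run_gblup_cv(
    pheno: PhenotypeTable,
    design: DesignSet,
    plan: SplitPlan,
    include_ge: bool | None = None,
) -> ProtocolResult:
    """GBLUP over the outer folds: REML fit on training, predict test.

    No tuning and no calibration; the design is row-sliced per fold so
    train and test share columns (and the Cholesky factor L).
    """
    if include_ge is None:
        include_ge = design.include_ge
    y = pheno.y
    oof = np.full(len(y), np.nan)
    outcomes = []
    for f, fold in enumerate(plan.folds):
        fit = fit_gblup(pheno.take(fold.train), design.take(fold.train),
                        include_ge=include_ge)
        yhat = predict_gblup(fit, design.take(fold.test))
        oof[fold.test] = yhat
        outcomes.append(FoldOutcome(
            fold=f, test_idx=fold.test, predictions=yhat,
            mse=float(np.mean((y[fold.test] - yhat) ** 2)),
            per_env_mse=_per_env_mse(y[fold.test], yhat,
                                     pheno.record_envs[fold.test]),
            n_train_final=len(fold.train),
            extras={"varcomp": fit.varcomp},
        ))
    method = "gblup_ge" if include_ge else "gblup"
    return ProtocolResult(method=method, folds=outcomes, oof_predictions=oof,
                          env_of_record=pheno.record_envs,
                          plan_seed=plan.seed, k=plan.k)
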