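"""Model fitting: inner-CV tuning of single configurations and the
budgeted auto-ensemble.

``tune_and_fit`` implements the single-algorithm approach: a registry
configuration is either fitted at its declared defaults or tuned by
Bayesian optimization of the inner 3-fold CV score (balanced accuracy for
classification, negative NMSE for regression), then refitted on the full
training data at the incumbent.

``auto_ensemble_fit`` implements the automated approach: candidate
(configuration, hyperparameter) pipelines are sampled and scored on
held-out inner-CV predictions until a budget is exhausted, then a
capped-size ensemble is assembled by greedy forward selection *with
replacement* on those held-out predictions; member weights are selection
frequencies.  The budget is a candidate-evaluation count by default (a
hardware-independent stand-in for a wall-clock training-time limit);
wall-clock seconds are available as an alternative mode.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold

from .metrics import balanced_accuracy, nmse
from .optimize import bayes_opt_minimize
from .registry import AlgorithmConfig
from .simulate import stage_seed

__all__ = [
    "FittedModel",
    "EnsembleModel",
    "EnsembleSearchSpec",
    "tune_and_fit",
    "auto_ensemble_fit",
    "predict",
    "hard_labels",
    "inner_cv_score",
]


@dataclass
class FittedModel:
    """A fitted configuration: estimator + the hyperparameters chosen."""

    config: AlgorithmConfig
    params: dict
    estimator: object
    inner_cv_score: float | None = None   # BACC or NMSE on inner folds

    @property
    def task(self) -> str:
        return self.config.task

    def predict(self, X) -> np.ndarray:
        return _scores(self.estimator, np.asarray(X, dtype=float), self.task)


@dataclass(frozen=True)
class EnsembleSearchSpec:
    """Budget and size cap for the auto-ensemble search."""

    budget: float = 60
    max_ensemble_size: int = 4
    budget_mode: Literal["evaluations", "seconds"] = "evaluations"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if self.max_ensemble_size < 1:
            raise ValueError("max_ensemble_size must be >= 1")


@dataclass
class EnsembleModel:
    """Weighted ensemble; prediction is the weighted mean of member scores."""

    members: list[tuple[FittedModel, float]]
    task: str
    inner_cv_score: float | None = None

    def __post_init__(self) -> None:
        w = np.array([w for _, w in self.members])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.stack([m.predict(X) for m, _ in self.members])
        w = np.array([w for _, w in self.members])
        return w @ preds


def hard_labels(scores: np.ndarray) -> np.ndarray:
    """Class-1 score threshold at 0.5; a score of exactly 0.5 is class 1."""
    return (np.asarray(scores) >= 0.5).astype(int)


def _scores(estimator, X: np.ndarray, task: str) -> np.ndarray:
    """Class-1 scores in [0, 1] for classifiers; real values for regressors."""
    if task == "regression":
        return np.asarray(estimator.predict(X), dtype=float)
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        classes = list(estimator.classes_)
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(len(X))  # degenerate single-class fit
    if hasattr(estimator, "decision_function"):
        d = np.asarray(estimator.decision_function(X), dtype=float)
        return 1.0 / (1.0 + np.exp(-d))
    labels = np.asarray(estimator.predict(X), dtype=float)
    return labels


def predict(model: FittedModel | EnsembleModel, X) -> np.ndarray:
    """Scores in [0, 1] (classification) or real values (regression)."""
    return model.predict(X)


def _fit(estimator, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return estimator


def _folds(y: np.ndarray, task: str, inner_folds: int, seed: int):
    if task == "classification":
        kf = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                             random_state=seed % (2**31))
    else:
        kf = KFold(n_splits=inner_folds, shuffle=True,
                   random_state=seed % (2**31))
    return list(kf.split(np.zeros(len(y)), y))


def _oof_predictions(estimator, X, y, folds, task: str) -> np.ndarray:
    """Held-out predictions for every training row via the inner folds."""
    oof = np.empty(len(y), dtype=float)
    for tr, te in folds:
        est = clone(estimator)
        _fit(est, X[tr], y[tr])
        oof[te] = _scores(est, X[te], task)
    return oof


def _score_predictions(y: np.ndarray, pred: np.ndarray, task: str) -> float:
    """Higher-is-better inner score: BACC, or -NMSE for regression."""
    if task == "classification":
        return balanced_accuracy(y, hard_labels(pred))
    return -nmse(y, pred)


def inner_cv_score(config: AlgorithmConfig, params: dict, X, y,
                   inner_folds: int, seed: int) -> float:
    """Mean held-out inner-CV score of a configuration (higher is better)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _folds(y, config.task, inner_folds, seed)
    oof = _oof_predictions(config.build(params, seed=seed), X, y, folds,
                           config.task)
    return _score_predictions(y, oof, config.task)


def tune_and_fit(config: AlgorithmConfig, X, y, inner_folds: int = 3,
                 n_opt_iters: int = 25, seed: int = 0) -> FittedModel:
    """Fit one registry configuration, tuning it in the inner CV loop.

    Defaults mode fits directly at the declared defaults.  bayes_opt mode
    minimizes (1 - BACC) or NMSE over the configuration's search space,
    evaluating the default point first, and refits on the full training
    data at the incumbent.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute first")
    if len(y) < inner_folds:
        raise ValueError(f"n={len(y)} smaller than inner_folds={inner_folds}")
    if config.task == "classification" and np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")

    if config.mode == "defaults":
        params = config.default_params()
        est = _fit(config.build(params, seed=seed), X, y)
        return FittedModel(config=config, params=params, estimator=est)

    folds = _folds(y, config.task, inner_folds, stage_seed(seed, "inner_folds"))

    def objective(params: dict) -> float:
        oof = _oof_predictions(config.build(params, seed=seed), X, y, folds,
                               config.task)
        return -_score_predictions(y, oof, config.task)

    result = bayes_opt_minimize(objective, config.space, n_iters=n_opt_iters,
                                seed=stage_seed(seed, "bayes_opt", config.id))
    est = _fit(config.build(result.best_params, seed=seed), X, y)
    return FittedModel(config=config, params=result.best_params, estimator=est,
                       inner_cv_score=-result.best_value)


def auto_ensemble_fit(X, y, spec: EnsembleSearchSpec,
                      registry: Sequence[AlgorithmConfig],
                      inner_folds: int = 3) -> EnsembleModel:
    """Budgeted algorithm search + greedy forward ensemble selection.

    Candidates are drawn from the registry (random hyperparameters inside
    each bayes_opt space; defaults for defaults-mode entries) and scored
    on held-out inner-CV predictions until the budget is exhausted.  The
    ensemble is then built by greedy forward selection with replacement on
    those held-out predictions, stopping early when no candidate improves
    the bag, capped at ``max_ensemble_size``; weights are selection
    frequencies.  Selected members are refitted on the full training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not registry:
        raise ValueError("registry is empty")
    task = registry[0].task
    rng = np.random.default_rng(stage_seed(spec.seed, "ensemble_search"))
    folds = _folds(y, task, inner_folds, stage_seed(spec.seed, "inner_folds"))

    candidates: list[tuple[AlgorithmConfig, dict, np.ndarray, float]] = []
    start = time.monotonic()
    n_eval = 0
    while True:
        if spec.budget_mode == "evaluations":
            if n_eval >= spec.budget:
                break
        elif n_eval > 0 and time.monotonic() - start >= spec.budget:
            break
        cfg = registry[int(rng.integers(len(registry)))]
        if cfg.space is not None and n_eval >= len(registry):
            params = cfg.space.from_unit(rng.random(len(cfg.space.dimensions)))
        elif cfg.space is not None and rng.random() < 0.5:
            params = cfg.space.from_unit(rng.random(len(cfg.space.dimensions)))
        else:
            params = cfg.default_params()
        try:
            oof = _oof_predictions(cfg.build(params, seed=spec.seed), X, y,
                                   folds, task)
        except Exception:
            n_eval += 1
            continue
        score = _score_predictions(y, oof, task)
        candidates.append((cfg, params, oof, score))
        n_eval += 1

    if not candidates:
        raise RuntimeError("budget too small: no candidate could be evaluated")

    # greedy forward selection with replacement on held-out predictions
    order = np.argsort([-c[3] for c in candidates])
    picks: list[int] = [int(order[0])]
    bag = candidates[picks[0]][2].copy()
    bag_score = candidates[picks[0]][3]
    while len(picks) < spec.max_ensemble_size:
        best_j, best_score = None, bag_score
        for j, (_, _, oof, _) in enumerate(candidates):
            trial = (bag * len(picks) + oof) / (len(picks) + 1)
            s = _score_predictions(y, trial, task)
            if s > best_score + 1e-12:
                best_j, best_score = j, s
        if best_j is None:
            break
        picks.append(best_j)
        bag = (bag * (len(picks) - 1) + candidates[best_j][2]) / len(picks)
        bag_score = best_score

    uniq, counts = np.unique(picks, return_counts=True)
    members = []
    for j, c in zip(uniq, counts):
        cfg, params, _, cand_score = candidates[int(j)]
        est = _fit(cfg.build(params, seed=spec.seed), X, y)
        members.append((FittedModel(config=cfg, params=params, estimator=est,
                                    inner_cv_score=cand_score),
                        float(c) / len(picks)))
    return EnsembleModel(members=members, task=task, inner_cv_score=bag_score)
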