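"""Outer cross-validation with late integration, ranking, and validation.

The outer loop holds out 25% of subjects per replication (stratified by
outcome or cohort).  Inside a replication everything is fitted on training
rows only: per-submodality imputation, standardization, and model tuning
in an inner 3-fold CV.  Each submodality model predicts the outer test
subjects for whom that block is observed; predictions are combined by
late integration (unweighted mean, or weights proportional to inner-CV
scores, renormalized over the blocks available per subject).  Scores are
balanced accuracy or NMSE, aggregated as mean + 95% percentile CI across
replications.

Ranking utilities implement the simulation-guided protocol: average
per-configuration scores over grid cells inside a low-SNR window, pick
the best / median / poorest configurations, then check whether their weak
order is preserved on target data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import MultimodalDataset, SubmodalityBlock, split_into_submodalities
from .learners import (
    EnsembleSearchSpec,
    FittedModel,
    auto_ensemble_fit,
    hard_labels,
    tune_and_fit,
)
from .metrics import ScoreSummary, balanced_accuracy, compare_algorithms, nmse, summarize
from .preprocess import (
    apply_imputer,
    apply_standardizer,
    fit_imputer,
    fit_standardizer,
    params_digest,
)
from .registry import AlgorithmConfig
from .simulate import stage_seed

__all__ = [
    "OuterCVSpec",
    "CVResult",
    "RankingReport",
    "outer_cv",
    "late_integrate",
    "rank_algorithms",
    "validate_ranking",
    "evaluate_grid",
]


@dataclass(frozen=True)
class OuterCVSpec:
    """Outer-loop geometry: 75/25 splits, replications, stratification."""

    test_fraction: float = 0.25
    n_replications: int = 10
    stratify_by: Literal["outcome", "cohort"] = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    def test_size(self, n: int) -> int:
        # round-half-up; remainder goes to training
        return int(np.floor(n * self.test_fraction + 0.5))


@dataclass
class ReplicationResult:
    replication: int
    test_ids: list
    submodality_scores: dict[str, np.ndarray]   # NaN where block unavailable
    integrated: np.ndarray
    score: float
    param_digest: str
    split_seed: int


@dataclass
class CVResult:
    """Per-replication predictions and scores plus the aggregate summary."""

    task: Literal["classification", "regression"]
    metric: str                       # "bacc" or "nmse"
    replications: list[ReplicationResult]
    spec: OuterCVSpec
    meta: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.replications])

    @property
    def chance_level(self) -> float:
        return 0.5 if self.metric == "bacc" else 1.0

    def summary(self) -> ScoreSummary:
        return summarize(self.scores, chance_level=self.chance_level,
                         higher_is_better=self.metric == "bacc")

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-replication table."""
        return pd.DataFrame({
            "replication": [r.replication for r in self.replications],
            "score": self.scores,
            "metric": self.metric,
            "n_test": [len(r.test_ids) for r in self.replications],
            "param_digest": [r.param_digest for r in self.replications],
        })

    def summary_dict(self) -> dict:
        s = self.summary()
        return {"metric": self.metric, "mean": s.mean,
                "ci": [s.ci_low, s.ci_high], "significant": s.significant,
                "n_replications": len(self.replications), **self.meta}


def late_integrate(predictions: np.ndarray, scheme: str = "mean",
                   weights: Sequence[float] | None = None) -> np.ndarray:
    """Combine per-submodality predictions into one prediction per subject.

    ``predictions`` is (n_subjects, n_submodalities) with NaN where a
    submodality has no prediction for a subject (block-wise missingness).
    mean: unweighted average of the available entries.  weighted: weights
    renormalized over the available submodalities per subject.
    """
    P = np.asarray(predictions, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    avail = ~np.isnan(P)
    if not avail.any(axis=1).all():
        i = int(np.where(~avail.any(axis=1))[0][0])
        raise ValueError(f"subject {i} has no available submodality prediction")
    if scheme == "mean":
        w = avail.astype(float)
    elif scheme == "weighted":
        if weights is None:
            raise ValueError("weighted scheme requires weights")
        w = avail * np.asarray(weights, dtype=float)[None, :]
        degenerate = w.sum(axis=1) <= 0
        w[degenerate] = avail[degenerate].astype(float)  # fall back to mean
    else:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    w = w / w.sum(axis=1, keepdims=True)
    return np.nansum(np.where(avail, P, 0.0) * w, axis=1)


def _strat_labels(dataset: MultimodalDataset, stratify_by: str,
                  y: np.ndarray) -> np.ndarray:
    if stratify_by == "outcome":
        return y if np.unique(y).size <= 10 else pd.qcut(y, 4, labels=False)
    cohort_cols = [c for c in dataset.covariates.columns
                   if c.startswith("cohort_")]
    if not cohort_cols:
        raise ValueError("no cohort covariate to stratify by")
    return dataset.covariates[cohort_cols].to_numpy().argmax(axis=1)


def _fit_submodality(block: SubmodalityBlock, train_idx: np.ndarray,
                     test_idx: np.ndarray, y: np.ndarray, task: str,
                     approach, imputation: str, inner_folds: int,
                     n_opt_iters: int, seed: int, need_weight: bool,
                     registry=None):
    """Train-only pipeline for one submodality; returns predictions on the
    available outer-test rows, the inner-CV weight, and a parameter digest."""
    avail = block.available
    tr = train_idx[avail[train_idx]]
    te = test_idx[avail[test_idx]]

    feats = np.asarray(block.X[block.feature_columns], dtype=float)
    covs = np.asarray(block.X[block.covariate_columns], dtype=float) \
        if block.covariate_columns else np.empty((len(block.X), 0))

    # drop feature columns with no observed training value (can happen when
    # block-wise holes remove most of a column's training rows)
    observed = ~np.isnan(feats[tr])
    keep = observed.any(axis=0)
    feats = feats[:, keep]

    if task == "classification" and np.unique(y[tr]).size < 2:
        raise _DegenerateSplit(block.name)
    if len(tr) < max(inner_folds, 2):
        raise _DegenerateSplit(block.name)

    imp = fit_imputer(feats[tr], method=imputation,
                      seed=stage_seed(seed, "imputer", block.name))
    Xtr = np.column_stack([apply_imputer(imp, feats[tr]), covs[tr]])
    std = fit_standardizer(Xtr)
    Xtr = apply_standardizer(std, Xtr)

    model_seed = stage_seed(seed, "model", block.name)
    if isinstance(approach, AlgorithmConfig):
        model = tune_and_fit(approach, Xtr, y[tr], inner_folds=inner_folds,
                             n_opt_iters=n_opt_iters, seed=model_seed)
        hyper = json.dumps(model.params, sort_keys=True, default=str)
        weights_repr = ""
    else:
        spec = EnsembleSearchSpec(budget=approach.budget,
                                  max_ensemble_size=approach.max_ensemble_size,
                                  budget_mode=approach.budget_mode,
                                  seed=model_seed)
        model = auto_ensemble_fit(Xtr, y[tr], spec, registry=registry,
                                  inner_folds=inner_folds)
        hyper = json.dumps([(m.config.id,
                             json.dumps(m.params, sort_keys=True, default=str))
                            for m, _ in model.members])
        weights_repr = json.dumps([w for _, w in model.members])

    weight = None
    if need_weight:
        weight = model.inner_cv_score
        if weight is None and isinstance(model, FittedModel):
            from .learners import inner_cv_score as _ics
            weight = _ics(model.config, model.params, Xtr, y[tr], inner_folds,
                          stage_seed(seed, "weight", block.name))

    digest = hashlib.sha256(
        (params_digest(imp, std) + hyper + weights_repr).encode()).hexdigest()

    preds = np.full(len(y), np.nan)
    if len(te):
        Xte = np.column_stack([apply_imputer(imp, feats[te]), covs[te]])
        Xte = apply_standardizer(std, Xte)
        preds[te] = model.predict(Xte)
    return preds, weight, digest


class _DegenerateSplit(Exception):
    """A training split unusable for this submodality (e.g. one class)."""


def outer_cv(dataset: MultimodalDataset,
             approach: AlgorithmConfig | EnsembleSearchSpec,
             task: Literal["classification", "regression"],
             spec: OuterCVSpec,
             integration_scheme: str = "mean",
             imputation: str = "median",
             inner_folds: int = 3,
             n_opt_iters: int = 25,
             registry: Sequence[AlgorithmConfig] | None = None) -> CVResult:
    """Run the full outer CV loop for one approach on one dataset.

    ``approach`` is either a single registry configuration (single-
    algorithm approach) or an :class:`EnsembleSearchSpec` (auto-ensemble
    approach; ``registry`` supplies its candidate pool).  Replications
    whose training split lacks a class are redrawn with a logged sub-seed.
    """
    if task == "classification":
        y = dataset.labels
        metric = "bacc"
    else:
        y = dataset.response
        metric = "nmse"
    if y is None:
        raise ValueError(f"dataset has no outcome for task {task!r}")
    if np.isnan(y).any():
        raise ValueError("outcomes contain missing entries")
    if isinstance(approach, EnsembleSearchSpec) and registry is None:
        raise ValueError("ensemble approach requires a registry")

    blocks = split_into_submodalities(dataset)
    strat = _strat_labels(dataset, spec.stratify_by, y)
    n = dataset.n_subjects
    test_size = spec.test_size(n)
    ids = np.asarray(dataset.subject_ids)

    replications: list[ReplicationResult] = []
    for r in range(spec.n_replications):
        # redraw on degenerate training splits, with a logged sub-seed
        for attempt in range(20):
            split_seed = stage_seed(spec.seed, "outer_split", r, attempt)
            tr_idx, te_idx = train_test_split(
                np.arange(n), test_size=test_size, stratify=strat,
                random_state=split_seed % (2**31))
            try:
                sub_preds, sub_weights, digests = {}, [], []
                for block in blocks:
                    preds, w, digest = _fit_submodality(
                        block, tr_idx, te_idx, y, task, approach,
                        imputation, inner_folds, n_opt_iters,
                        stage_seed(spec.seed, "rep", r),
                        need_weight=integration_scheme == "weighted",
                        registry=registry)
                    sub_preds[block.name] = preds
                    sub_weights.append(w)
                    digests.append(digest)
                break
            except _DegenerateSplit:
                continue
        else:
            raise RuntimeError(f"replication {r}: no usable split found")

        P = np.column_stack([sub_preds[b.name][te_idx] for b in blocks])
        if integration_scheme == "weighted":
            raw = np.array([np.nan if wi is None else float(wi)
                            for wi in sub_weights])
            if metric == "bacc":
                w = np.maximum(raw - 0.5, 0.0)     # excess BACC over chance
            else:
                w = np.maximum(1.0 + raw, 0.0)     # 1 - NMSE (raw is -NMSE)
            w = np.where(np.isnan(w), 0.0, w)
            integrated = late_integrate(P, "weighted", weights=w)
        else:
            integrated = late_integrate(P, "mean")

        if metric == "bacc":
            score = balanced_accuracy(y[te_idx], hard_labels(integrated))
        else:
            score = nmse(y[te_idx], integrated)

        rep_digest = hashlib.sha256("".join(digests).encode()).hexdigest()
        replications.append(ReplicationResult(
            replication=r, test_ids=list(ids[te_idx]),
            submodality_scores=sub_preds, integrated=integrated,
            score=score, param_digest=rep_digest, split_seed=split_seed))

    meta = {"approach": (approach.id if isinstance(approach, AlgorithmConfig)
                         else "ensemble"),
            "integration": integration_scheme, "imputation": imputation}
    if isinstance(dataset.meta.get("snr_db"), (int, float)):
        meta["snr_db"] = dataset.meta["snr_db"]
        meta["variant"] = dataset.meta.get("variant")
    return CVResult(task=task, metric=metric, replications=replications,
                    spec=spec, meta=meta)


# ---------------------------------------------------------------------------
# simulation-guided ranking

@dataclass
class RankingReport:
    """Best/median/poorest selection on simulated data + transfer check."""

    selection_scores: dict[str, float]     # config id -> mean score in window
    best: str
    median: str
    poorest: str
    snr_window: tuple[float, float]
    higher_is_better: bool = True
    transfer_scores: dict[str, float] | None = None
    ranking_preserved: bool | None = None
    pairwise_p: dict[str, float] | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["snr_window"] = list(self.snr_window)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RankingReport":
        d = json.loads(text)
        d["snr_window"] = tuple(d["snr_window"])
        return cls(**d)


def rank_algorithms(grid_results: pd.DataFrame,
                    snr_window: tuple[float, float] = (-20.0, 0.0),
                    higher_is_better: bool = True) -> RankingReport:
    """Average per-config scores over grid cells inside the SNR window and
    select the best, median (lower-middle on even counts) and poorest.

    ``grid_results`` is tidy with columns ``config_id``, ``snr_db`` and
    ``score`` (one row per config per grid cell).
    """
    lo, hi = snr_window
    window = grid_results[(grid_results["snr_db"] >= lo)
                          & (grid_results["snr_db"] <= hi)]
    if window.empty:
        raise ValueError("no grid cells inside the SNR window")
    means = window.groupby("config_id")["score"].mean()
    # sort best-first; median = lower-middle of the best-first order
    means = means.sort_values(ascending=not higher_is_better)
    ids = list(means.index)
    m = len(ids)
    return RankingReport(
        selection_scores={k: float(v) for k, v in means.items()},
        best=ids[0],
        median=ids[(m - 1) // 2],
        poorest=ids[-1],
        snr_window=(float(lo), float(hi)),
        higher_is_better=higher_is_better,
    )


def validate_ranking(report: RankingReport, target_dataset: MultimodalDataset,
                     task: Literal["classification", "regression"],
                     cv_spec: OuterCVSpec, **cv_kwargs) -> RankingReport:
    """Run outer CV for the three selected configs on target data and check
    whether their weak order is preserved; attaches pairwise p-values."""
    from .registry import get_config

    if not (report.best and report.median and report.poorest):
        raise ValueError("report lacks best/median/poorest selections")
    selected = [report.best, report.median, report.poorest]
    results = {}
    for cid in dict.fromkeys(selected):  # unique, order kept
        res = outer_cv(target_dataset, get_config(cid), task, cv_spec,
                       **cv_kwargs)
        results[cid] = res
    means = {cid: float(res.scores.mean()) for cid, res in results.items()}
    sgn = 1.0 if report.higher_is_better else -1.0
    preserved = (sgn * means[report.best] >= sgn * means[report.median]
                 >= sgn * means[report.poorest])
    pairs = {}
    for a, b in [(report.best, report.median), (report.median, report.poorest),
                 (report.best, report.poorest)]:
        if a != b:
            pairs[f"{a}|{b}"] = compare_algorithms(
                results[a].scores, results[b].scores, seed=cv_spec.seed)
    report.transfer_scores = {cid: means[cid] for cid in dict.fromkeys(selected)}
    report.ranking_preserved = bool(preserved)
    report.pairwise_p = pairs
    return report


def evaluate_grid(datasets: Sequence[MultimodalDataset],
                  configs: Sequence[AlgorithmConfig],
                  task: Literal["classification", "regression"],
                  cv_spec: OuterCVSpec, **cv_kwargs) -> pd.DataFrame:
    """Score every config on every grid dataset; tidy per-cell results."""
    rows = []
    for ds in datasets:
        for cfg in configs:
            res = outer_cv(ds, cfg, task, cv_spec, **cv_kwargs)
            rows.append({
                "config_id": cfg.id,
                "snr_db": ds.meta.get("snr_db"),
                "variant": ds.meta.get("variant"),
                "seed": ds.meta.get("seed"),
                "score": float(res.scores.mean()),
                "metric": res.metric,
            })
    return pd.DataFrame(rows)
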