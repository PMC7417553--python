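"""Performance measures, CV confidence intervals, and paired comparisons.

Balanced accuracy (BACC) is the mean of sensitivity and specificity: 0.5
at chance regardless of class imbalance, 1 at perfection.  Normalized mean
squared error (NMSE) divides the MSE by the *population* variance of the
true outcomes on the evaluation split, so a predictor that always outputs
the mean of the evaluated outcomes scores exactly 1 (chance level).

Confidence intervals over cross-validation replications are percentile
intervals (2.5th/97.5th), which reproduce degenerate [c, c] intervals for
constant predictors.  Pairwise algorithm comparison uses a two-sided
paired sign-flip permutation test on per-replication score differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import balanced_accuracy_score

__all__ = [
    "balanced_accuracy",
    "nmse",
    "summarize",
    "compare_algorithms",
    "ScoreSummary",
]


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2 for binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if np.unique(y_true).size < 2:
        raise ValueError("y_true contains a single class")
    return float(balanced_accuracy_score(y_true, y_pred))


def nmse(y_true, y_pred) -> float:
    """mean((y_true - y_pred)^2) / Var(y_true), population variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least two evaluation points")
    var = np.var(y_true)  # population convention: mean predictor -> exactly 1
    if var == 0:
        raise ValueError("y_true has zero variance")
    return float(np.mean((y_true - y_pred) ** 2) / var)


@dataclass
class ScoreSummary:
    mean: float
    ci_low: float
    ci_high: float
    significant: bool
    chance_level: float
    higher_is_better: bool

    def as_tuple(self) -> tuple[float, tuple[float, float], bool]:
        return self.mean, (self.ci_low, self.ci_high), self.significant


def summarize(scores, chance_level: float,
              higher_is_better: bool = True) -> ScoreSummary:
    """Mean + 95% percentile CI across replications; significance flag.

    Significant iff the CI excludes the chance level on the favorable side
    (entirely above chance for BACC, entirely below for NMSE).
    """
    scores = np.asarray(scores, dtype=float)
    mean = float(scores.mean())
    lo = float(np.percentile(scores, 2.5))
    hi = float(np.percentile(scores, 97.5))
    if higher_is_better:
        significant = lo > chance_level
    else:
        significant = hi < chance_level
    return ScoreSummary(mean=mean, ci_low=lo, ci_high=hi,
                        significant=bool(significant),
                        chance_level=chance_level,
                        higher_is_better=higher_is_better)


def compare_algorithms(scores_a, scores_b, n_permutations: int = 10_000,
                       seed: int = 0) -> float:
    """Two-sided paired sign-flip permutation p-value on score differences.

    The statistic is the mean per-replication difference; under the null
    the sign of each paired difference is exchangeable.  The add-one
    Monte-Carlo estimator is used, so p is never exactly 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    observed = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    perm_stats = np.abs((signs * d).mean(axis=1))
    n_extreme = int(np.sum(perm_stats >= observed - 1e-12))
    return float((1 + n_extreme) / (1 + n_permutations))
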