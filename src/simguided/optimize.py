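"""Sequential model-based optimization: expected improvement over a GP.

Minimizes a black-box objective over a bounded hyperparameter space.  The
first evaluation is always the declared default point, so the incumbent
can never be worse than the default configuration; a fixed fraction of
iterations explore uniformly at random; the rest maximize expected
improvement under a Gaussian-process surrogate over the unit cube
(log-scaled dimensions are optimized in log space).  Fully deterministic
given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = ["Dimension", "SearchSpace", "bayes_opt_minimize", "OptResult"]


@dataclass(frozen=True)
class Dimension:
    """One hyperparameter: real or integer range, or categorical choices."""

    name: str
    low: float | None = None
    high: float | None = None
    log: bool = False
    integer: bool = False
    choices: tuple | None = None

    def __post_init__(self) -> None:
        if self.choices is None:
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"dimension {self.name!r} needs low < high")
            if self.log and self.low <= 0:
                raise ValueError(f"log dimension {self.name!r} needs low > 0")

    # -- mapping to/from the unit interval -------------------------------
    def to_unit(self, value) -> float:
        if self.choices is not None:
            return self.choices.index(value) / max(len(self.choices) - 1, 1)
        lo, hi = ((np.log(self.low), np.log(self.high)) if self.log
                  else (self.low, self.high))
        v = np.log(value) if self.log else float(value)
        return float((v - lo) / (hi - lo))

    def from_unit(self, u: float):
        u = float(np.clip(u, 0.0, 1.0))
        if self.choices is not None:
            idx = int(round(u * (len(self.choices) - 1)))
            return self.choices[idx]
        lo, hi = ((np.log(self.low), np.log(self.high)) if self.log
                  else (self.low, self.high))
        v = lo + u * (hi - lo)
        if self.log:
            v = np.exp(v)
        if self.integer:
            return int(round(v))
        return float(v)

    def contains(self, value) -> bool:
        if self.choices is not None:
            return value in self.choices
        return self.low <= value <= self.high


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]
    defaults: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must be non-empty")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    def default_point(self) -> dict:
        out = {}
        for d in self.dimensions:
            if d.name in self.defaults:
                out[d.name] = self.defaults[d.name]
            elif d.choices is not None:
                out[d.name] = d.choices[0]
            else:
                out[d.name] = d.from_unit(0.5)
        return out

    def contains(self, params: dict) -> bool:
        return all(d.contains(params[d.name]) for d in self.dimensions)

    def to_unit(self, params: dict) -> np.ndarray:
        return np.array([d.to_unit(params[d.name]) for d in self.dimensions])

    def from_unit(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(ui) for d, ui in zip(self.dimensions, u)}


@dataclass
class OptResult:
    best_params: dict
    best_value: float
    evaluated: list[tuple[dict, float]]


def bayes_opt_minimize(objective: Callable[[dict], float], space: SearchSpace,
                       n_iters: int = 25, seed: int = 0,
                       explore_fraction: float = 0.2,
                       n_candidates: int = 256) -> OptResult:
    """Minimize ``objective`` over ``space`` with ``n_iters`` evaluations.

    Iteration 1 evaluates the space's default point; afterwards each
    iteration either explores uniformly (probability ``explore_fraction``)
    or evaluates the expected-improvement maximizer over a random
    candidate pool under a Matern-5/2 GP fitted to the history.
    """
    rng = np.random.default_rng(seed)
    X: list[np.ndarray] = []
    y: list[float] = []
    evaluated: list[tuple[dict, float]] = []

    def _eval(params: dict) -> None:
        val = float(objective(params))
        X.append(space.to_unit(params))
        y.append(val)
        evaluated.append((params, val))

    _eval(space.default_point())
    d = len(space.dimensions)

    for _ in range(1, n_iters):
        if rng.random() < explore_fraction or len(y) < 3:
            u = rng.random(d)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(length_scale=np.full(d, 0.3), nu=2.5),
                alpha=1e-6, normalize_y=True, random_state=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.vstack(X), np.asarray(y))
            cand = rng.random((n_candidates, d))
            mu, sd = gp.predict(cand, return_std=True)
            best = min(y)
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        _eval(space.from_unit(u))

    i_best = int(np.argmin(y))
    return OptResult(best_params=evaluated[i_best][0], best_value=y[i_best],
                     evaluated=evaluated)
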