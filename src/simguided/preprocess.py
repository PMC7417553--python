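"""Train-only imputation and standardization with a strict fit/apply contract.

Every parameter here is derived exclusively from training rows; ``apply_*``
never updates state.  This is what keeps the outer test set untouched by
the preprocessing stage of the nested cross-validation.

Two imputers are provided, matching the two methods benchmarked on
simulated data before any real-data analysis: per-feature median
imputation, and probabilistic PCA (x = W z + mu + eps, eps ~ N(0, s2 I))
fitted by an EM algorithm that treats missing cells as additional latent
variables, so the observed-data log-likelihood is non-decreasing across
iterations.  PPCA imputes a missing cell by its posterior mean given the
row's observed entries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ImputerParams",
    "StandardizerParams",
    "fit_imputer",
    "apply_imputer",
    "fit_standardizer",
    "apply_standardizer",
    "params_digest",
]


@dataclass
class ImputerParams:
    """Fitted imputation parameters (training rows only)."""

    method: Literal["median", "ppca"]
    medians: np.ndarray | None = None          # (p,)
    W: np.ndarray | None = None                # (p, k)
    mu: np.ndarray | None = None               # (p,)
    sigma2: float | None = None
    k: int | None = None
    converged: bool = True
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "method": self.method,
            "medians": None if self.medians is None else self.medians.tolist(),
            "W": None if self.W is None else self.W.tolist(),
            "mu": None if self.mu is None else self.mu.tolist(),
            "sigma2": self.sigma2,
            "k": self.k,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        return json.dumps(d, sort_keys=True)


@dataclass
class StandardizerParams:
    """Per-feature training mean and sample sd (n-1 denominator)."""

    mean: np.ndarray
    sd: np.ndarray

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "sd": self.sd.tolist()},
                          sort_keys=True)


def params_digest(*params) -> str:
    """Stable hash of fitted parameters, for the leakage audit trail."""
    h = hashlib.sha256()
    for p in params:
        h.update(p.to_json().encode())
    return h.hexdigest()


def _as_masked(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(block, dtype=float)
    return X, np.isnan(X)


# ---------------------------------------------------------------------------
# PPCA with missing data (EM over latent z and the missing cells)

def _ppca_loglik(X: np.ndarray, miss: np.ndarray, W: np.ndarray,
                 mu: np.ndarray, s2: float) -> float:
    """Observed-data log-likelihood: each row's observed part is Gaussian
    with mean mu_O and covariance W_O W_O' + s2 I."""
    ll = 0.0
    for i in range(X.shape[0]):
        obs = ~miss[i]
        if not obs.any():
            continue
        xo = X[i, obs] - mu[obs]
        Wo = W[obs]
        C = Wo @ Wo.T + s2 * np.eye(obs.sum())
        sign, logdet = np.linalg.slogdet(C)
        ll += -0.5 * (obs.sum() * np.log(2 * np.pi) + logdet
                      + xo @ np.linalg.solve(C, xo))
    return float(ll)


def _fit_ppca(X: np.ndarray, miss: np.ndarray, k: int, max_iter: int,
              tol: float, seed: int) -> ImputerParams:
    n, p = X.shape
    if k < 1:
        raise ValueError("ppca requires k >= 1")
    k = min(k, p - 1) if p > 1 else 1

    # init from mean-imputed SVD
    col_mean = np.nanmean(X, axis=0)
    X0 = np.where(miss, col_mean, X)
    mu = X0.mean(axis=0)
    Xc = X0 - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rng = np.random.default_rng(seed)
    W = Vt[:k].T * (s[:k] / np.sqrt(max(n, 1)))
    W = W + 1e-6 * rng.standard_normal(W.shape)
    resid = max(np.mean(Xc**2) - np.sum((s[:k] / np.sqrt(n))**2) / p, 1e-6)
    s2 = float(resid)

    ll_path: list[float] = []
    converged = False
    it = 0
    Ik = np.eye(k)
    for it in range(1, max_iter + 1):
        # E-step: per row, posterior of z given observed entries, and
        # expectations of the missing cells
        S_zz = np.zeros((k + 1, k + 1))          # sum of E[[z;1][z;1]']
        S_xz = np.zeros((p, k + 1))              # sum of E[x [z;1]']
        S_xx = np.zeros(p)                       # sum of E[x_j^2]
        for i in range(n):
            obs = ~miss[i]
            Wo = W[obs]
            M = Wo.T @ Wo + s2 * Ik
            Minv = np.linalg.inv(M)
            Ez = Minv @ Wo.T @ (X[i, obs] - mu[obs]) if obs.any() else np.zeros(k)
            Czz = s2 * Minv if obs.any() else Ik
            Ezz = Czz + np.outer(Ez, Ez)

            Ex = np.where(obs, X[i], W @ Ez + mu)
            # E[x z'] : observed rows x_j E[z]'; missing rows W_j Ezz + mu_j E[z]'
            Exz = np.empty((p, k))
            Exz[obs] = np.outer(X[i, obs], Ez)
            if (~obs).any():
                Exz[~obs] = W[~obs] @ Ezz + np.outer(mu[~obs], Ez)
            # E[x_j^2]
            Ex2 = np.empty(p)
            Ex2[obs] = X[i, obs] ** 2
            if (~obs).any():
                Wm = W[~obs]
                Ex2[~obs] = (s2 + np.einsum("ij,jk,ik->i", Wm, Ezz, Wm)
                             + 2 * mu[~obs] * (Wm @ Ez) + mu[~obs] ** 2)

            zt = np.concatenate([Ez, [1.0]])
            blk = np.empty((k + 1, k + 1))
            blk[:k, :k] = Ezz
            blk[:k, k] = Ez
            blk[k, :k] = Ez
            blk[k, k] = 1.0
            S_zz += blk
            S_xz += np.column_stack([Exz, Ex])
            S_xx += Ex2

        # M-step: joint regression of x on [z; 1]
        A = S_xz @ np.linalg.inv(S_zz)           # (p, k+1) = [W_new, mu_new]
        W_new, mu_new = A[:, :k], A[:, k]
        # s2 = mean E[(x_j - W_j z - mu_j)^2]; using the normal equations
        # this collapses to (S_xx - sum_j A_j . S_xz_j) / (n p)
        s2_new = float((S_xx.sum() - np.einsum("jk,jk->", A, S_xz)) / (n * p))
        s2_new = max(s2_new, 1e-12)

        W, mu, s2 = W_new, mu_new, s2_new
        ll = _ppca_loglik(X, miss, W, mu, s2)
        ll_path.append(ll)
        if len(ll_path) > 1:
            denom = max(abs(ll_path[-2]), 1.0)
            if abs(ll_path[-1] - ll_path[-2]) / denom < tol:
                converged = True
                break

    return ImputerParams(method="ppca", W=W, mu=mu, sigma2=s2, k=k,
                         converged=converged, n_iter=it, loglik_path=ll_path)


# ---------------------------------------------------------------------------
# public fit/apply

def fit_imputer(train_block: np.ndarray, method: Literal["median", "ppca"],
                k: int | None = None, max_iter: int = 500,
                tol: float = 1e-6, seed: int = 0) -> ImputerParams:
    """Fit an imputer on training rows only.

    Every feature must have at least one observed training value.  PPCA
    defaults to k = min(5, p - 1); EM runs until the relative change in
    observed-data log-likelihood drops below ``tol`` or ``max_iter``.
    """
    X, miss = _as_masked(train_block)
    if X.ndim != 2:
        raise ValueError("train_block must be 2-D")
    all_missing = miss.all(axis=0)
    if all_missing.any():
        j = int(np.where(all_missing)[0][0])
        raise ValueError(f"feature column {j} has no observed training value")
    if method == "median":
        return ImputerParams(method="median",
                             medians=np.nanmedian(X, axis=0))
    if method == "ppca":
        if k is None:
            k = min(5, max(X.shape[1] - 1, 1))
        return _fit_ppca(X, miss, k=k, max_iter=max_iter, tol=tol, seed=seed)
    raise ValueError(f"unknown imputation method {method!r}")


def apply_imputer(params: ImputerParams, block: np.ndarray) -> np.ndarray:
    """Fill missing entries; observed entries pass through unchanged.

    Median: per-feature training median.  PPCA: posterior mean of the
    missing cells conditional on the row's observed entries.
    """
    X, miss = _as_masked(block)
    out = X.copy()
    if params.method == "median":
        if X.shape[1] != params.medians.shape[0]:
            raise ValueError("feature count differs from fitted parameters")
        out[miss] = np.broadcast_to(params.medians, X.shape)[miss]
        return out
    W, mu, s2, k = params.W, params.mu, params.sigma2, params.k
    if X.shape[1] != W.shape[0]:
        raise ValueError("feature count differs from fitted parameters")
    Ik = np.eye(k)
    for i in range(X.shape[0]):
        if not miss[i].any():
            continue
        obs = ~miss[i]
        Wo = W[obs]
        M = Wo.T @ Wo + s2 * Ik
        Ez = np.linalg.solve(M, Wo.T @ (X[i, obs] - mu[obs])) if obs.any() \
            else np.zeros(k)
        out[i, miss[i]] = W[miss[i]] @ Ez + mu[miss[i]]
    return out


def fit_standardizer(train_block: np.ndarray) -> StandardizerParams:
    """Per-feature mean and sample sd from training rows (no missing values).

    A zero-variance training feature gets sd = 1, so it is centered only
    and keeps its column (shapes stay stable mid-CV).
    """
    X = np.asarray(train_block, dtype=float)
    if np.isnan(X).any():
        raise ValueError("standardizer requires imputation first (NaNs present)")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    return StandardizerParams(mean=mean, sd=sd)


def apply_standardizer(params: StandardizerParams, block: np.ndarray) -> np.ndarray:
    X = np.asarray(block, dtype=float)
    if X.shape[1] != params.mean.shape[0]:
        raise ValueError("feature count differs from fitted parameters")
    return (X - params.mean) / params.sd
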