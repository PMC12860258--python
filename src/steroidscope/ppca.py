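"""Probabilistic PCA with missing data, and multiple imputation.

Model: ``x = mu + W t + eps`` with latent scores ``t ~ N(0, I_k)`` and
isotropic noise ``eps ~ N(0, sigma2 I_d)``.  Missing cells are treated as
latent variables alongside the scores, so the EM fit uses every observed
cell.  Imputations are drawn from the exact Gaussian conditional of the
missing cells given a row's observed cells under the fitted model, which is
what makes the completed data sets "multiple" rather than single best
guesses.

EM details: the E-step computes, per row, the posterior moments of ``t``
and of the missing cells given the observed entries; the M-step updates the
augmented loading matrix ``[W, mu]`` and ``sigma2`` in closed form from the
accumulated sufficient statistics.  The observed-data log-likelihood is
evaluated every iteration (via the Woodbury identity) and is monotonically
non-decreasing — an invariant the test suite enforces.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class PPCAModel:
    W: np.ndarray            # (d, k) loadings
    mu: np.ndarray           # (d,) feature means
    sigma2: float            # isotropic noise variance (> 0)
    k: int
    loglik_trace: np.ndarray
    converged: bool


@dataclasses.dataclass
class ImputationSet:
    """M completed matrices; observed cells identical across all of them."""

    matrices: list[np.ndarray]
    model: PPCAModel
    seeds: list[int]

    @property
    def m(self) -> int:
        return len(self.matrices)


def choose_k(X: np.ndarray, threshold: float = 0.80, k_max: int | None = None) -> int:
    """Smallest k explaining >= ``threshold`` variance on complete columns.

    Falls back to mean-imputed PCA when fewer than 3 columns are complete.
    """
    X = np.asarray(X, float)
    complete = ~np.isnan(X).any(axis=0)
    if complete.sum() >= 3:
        Xc = X[:, complete]
    else:
        Xc = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    Xc = Xc - Xc.mean(0)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, threshold) + 1)
    lim = min(X.shape[0] - 1, X.shape[1] - 1)
    if k_max is not None:
        lim = min(lim, k_max)
    return max(1, min(k, lim))


def _posterior_t(W: np.ndarray, sigma2: float, obs: np.ndarray,
                 resid_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior mean/cov of t given a row's observed residuals.

    Also returns that row's observed-data log-likelihood contribution.
    """
    Wo = W[obs]
    k = W.shape[1]
    M = Wo.T @ Wo + sigma2 * np.eye(k)
    b = Wo.T @ resid_obs
    Minv = np.linalg.inv(M)
    t_hat = Minv @ b
    cov_t = sigma2 * Minv
    do = obs.sum()
    sign, logdetM = np.linalg.slogdet(M)
    logdetC = (do - k) * np.log(sigma2) + logdetM
    quad = (resid_obs @ resid_obs - b @ Minv @ b) / sigma2
    ll = -0.5 * (do * _LOG2PI + logdetC + quad)
    return t_hat, cov_t, ll


def fit_ppca(X: np.ndarray, k: int, tol: float = 1e-6,
             max_iter: int = 500, min_sigma2: float = 1e-12) -> PPCAModel:
    """Fit PPCA by EM on a matrix with NaN-coded missing cells."""
    X = np.asarray(X, float)
    n, d = X.shape
    if k >= d:
        raise ValueError(f"k={k} must be < number of features ({d})")
    if k >= n:
        raise ValueError(f"k={k} must be < number of rows ({n})")
    miss = np.isnan(X)
    all_missing = np.where(miss.all(axis=1))[0]
    if all_missing.size:
        raise ValueError(f"row(s) with no observed cell: {all_missing[:5].tolist()}")

    # init: mean-impute then SVD
    mu = np.nanmean(X, axis=0)
    X0 = np.where(miss, mu, X) - mu
    U, s, Vt = np.linalg.svd(X0, full_matrices=False)
    W = Vt[:k].T * (s[:k] / np.sqrt(n))
    total_var = (X0 ** 2).sum() / (n * d)
    sigma2 = max(float(total_var - (s[:k] ** 2).sum() / (n * d)), 1e-3 * total_var,
                 min_sigma2)

    obs_rows = [~miss[i] for i in range(n)]
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        S_tt = np.zeros((k + 1, k + 1))
        S_xt = np.zeros((d, k + 1))
        Ex2_sum = 0.0
        ll = 0.0
        for i in range(n):
            obs = obs_rows[i]
            x = X[i]
            resid = x[obs] - mu[obs]
            t_hat, cov_t, ll_i = _posterior_t(W, sigma2, obs, resid)
            ll += ll_i
            Ett = cov_t + np.outer(t_hat, t_hat)
            S_tt[:k, :k] += Ett
            S_tt[:k, k] += t_hat
            S_tt[k, :k] += t_hat
            # E[x] and E[x t^T]
            mis = ~obs
            ex = x.copy()
            Wm = W[mis]
            ex[mis] = mu[mis] + Wm @ t_hat
            S_xt[:, k] += ex
            S_xt[obs, :k] += np.outer(x[obs], t_hat)
            S_xt[mis, :k] += np.outer(ex[mis], t_hat) + Wm @ cov_t
            # E[sum x^2]
            var_m = np.einsum("ij,jk,ik->i", Wm, cov_t, Wm) + sigma2
            Ex2_sum += float(x[obs] @ x[obs]) + float((ex[mis] ** 2).sum()
                                                      + var_m.sum())
        S_tt[k, k] = n
        trace.append(ll)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if (trace[-1] - trace[-2]) / denom < tol:
                converged = True
                break
        C = np.linalg.solve(S_tt, S_xt.T).T       # [W, mu] update
        sigma2_new = (Ex2_sum - float((C * S_xt).sum())) / (n * d)
        W, mu = C[:, :k], C[:, k]
        if sigma2_new <= min_sigma2:
            # noise variance has collapsed (noise-free data); further EM
            # steps are numerically meaningless, stop with a clean trace
            sigma2 = min_sigma2
            converged = True
            break
        sigma2 = float(sigma2_new)

    return PPCAModel(W=W, mu=mu, sigma2=sigma2, k=k,
                     loglik_trace=np.asarray(trace), converged=converged)


def conditional_moments(model: PPCAModel, x: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of a row's missing cells given its observed cells."""
    obs = ~np.isnan(x)
    mis = ~obs
    t_hat, cov_t, _ = _posterior_t(model.W, model.sigma2, obs, x[obs] - model.mu[obs])
    Wm = model.W[mis]
    mean = model.mu[mis] + Wm @ t_hat
    cov = Wm @ cov_t @ Wm.T + model.sigma2 * np.eye(int(mis.sum()))
    return mean, cov


def draw_imputations(model: PPCAModel, X: np.ndarray, M: int,
                     seed: int) -> ImputationSet:
    """Draw M completed matrices from the posterior predictive.

    Per row, missing cells are sampled from the exact Gaussian conditional
    of the PPCA joint given the observed cells; observed cells are copied
    through untouched.
    """
    if M < 2:
        raise ValueError("multiple imputation requires M >= 2")
    X = np.asarray(X, float)
    n, _ = X.shape
    seeds = [int(seed) + 1000 * m for m in range(M)]
    miss = np.isnan(X)
    k = model.k
    mats = []
    for m, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        out = X.copy()
        for i in range(n):
            mis = miss[i]
            if not mis.any():
                continue
            obs = ~mis
            t_hat, cov_t, _ = _posterior_t(model.W, model.sigma2, obs,
                                           X[i, obs] - model.mu[obs])
            # x_mis | x_obs = mu_m + W_m t + eps, with t ~ N(t_hat, cov_t)
            L = np.linalg.cholesky(cov_t + 1e-15 * np.eye(k))
            t_draw = t_hat + L @ rng.standard_normal(k)
            Wm = model.W[mis]
            out[i, mis] = (model.mu[mis] + Wm @ t_draw
                           + np.sqrt(model.sigma2) * rng.standard_normal(int(mis.sum())))
        mats.append(out)
    return ImputationSet(matrices=mats, model=model, seeds=seeds)
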