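"""Full-covariance Gaussian mixtures fitted by EM under missing data.

Rows of the variability matrix may miss entire domains (too few prompts).
The E-step evaluates component responsibilities from the marginal normal
density of each row's *observed* coordinates; the M-step replaces missing
coordinates by their conditional expectations

    E[x_mis | x_obs, k] = mu_mis + S_mo S_oo^{-1} (x_obs - mu_obs)

and adds the conditional covariance S_mis|obs into the scatter update, so
the observed-data log-likelihood is non-decreasing.  Model order is
chosen by BIC = -2 loglik + p ln(n) with p = (K-1) + K d + K d(d+1)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GmmModel:
    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, d)
    covariances: np.ndarray        # (K, d, d)
    loglik_trace: np.ndarray
    responsibilities: np.ndarray   # (n, K)
    labels: np.ndarray             # hard assignments, argmax gamma
    n_params: int
    bic: float | None = None
    converged: bool = True
    settings: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def n_free_params(K: int, d: int) -> int:
    return (K - 1) + K * d + K * d * (d + 1) // 2


class _Pattern:
    """Precomputed index machinery for one missing-data pattern."""

    __slots__ = ("o", "m", "rows", "oo", "mo", "mm", "Xo")

    def __init__(self, o, m, rows, X):
        self.o, self.m, self.rows = o, m, rows
        self.oo = np.ix_(o, o)
        self.mo = np.ix_(m, o) if m.size else None
        self.mm = np.ix_(m, m) if m.size else None
        self.Xo = X[np.ix_(rows, o)]


def _pattern_groups(X: np.ndarray):
    """Group row indices by missing-data pattern."""
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = np.flatnonzero(~obs.any(axis=1))
        raise ValueError(f"rows with no observed entries: {bad.tolist()}")
    d = X.shape[1]
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for g in range(len(patterns)):
        o = np.flatnonzero(patterns[g])
        m = np.flatnonzero(~patterns[g])
        out.append(_Pattern(o, m, np.flatnonzero(inverse == g), X))
    return out


def _estep(X, groups, weights, means, covs):
    """Log-responsibilities and observed-data log-likelihood."""
    n, _ = X.shape
    K = len(weights)
    logr = np.full((n, K), -np.inf)
    for g in groups:
        for k in range(K):
            Soo = covs[k][g.oo]
            L = np.linalg.cholesky(Soo)
            dev = g.Xo - means[k][g.o]
            sol = np.linalg.solve(Soo, dev.T)
            maha = np.einsum("ij,ji->i", dev, sol)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            logr[g.rows, k] = -0.5 * (len(g.o) * _LOG2PI + logdet + maha)
    logr = logr + np.log(weights)
    norm = logsumexp(logr, axis=1)
    return logr - norm[:, None], float(norm.sum())


def _mstep(X, groups, gamma, means, covs, ridge):
    n, d = X.shape
    K = gamma.shape[1]
    Nk = gamma.sum(axis=0)
    new_means = np.zeros((K, d))
    new_covs = np.zeros((K, d, d))
    for k in range(K):
        acc_mu = np.zeros(d)
        acc_S = np.zeros((d, d))
        for g in groups:
            w = gamma[g.rows, k]
            xhat = np.empty((len(g.rows), d))
            xhat[:, g.o] = g.Xo
            if g.m.size:
                Soo = covs[k][g.oo]
                Smo = covs[k][g.mo]
                B = np.linalg.solve(Soo, Smo.T).T        # S_mo S_oo^-1
                xhat[:, g.m] = means[k][g.m] + (g.Xo - means[k][g.o]) @ B.T
                Cmm = covs[k][g.mm] - B @ Smo.T          # conditional cov
                acc_S[g.mm] += w.sum() * Cmm
            acc_mu += w @ xhat
            acc_S += (xhat * w[:, None]).T @ xhat
        mu = acc_mu / Nk[k]
        S = acc_S / Nk[k] - np.outer(mu, mu)
        S = 0.5 * (S + S.T)
        S += ridge * np.mean(np.diag(S)) * np.eye(d)
        new_means[k] = mu
        new_covs[k] = S
    return Nk / n, new_means, new_covs


def _init_params(X, K, rng, use_kmeans):
    n, d = X.shape
    complete = ~np.isnan(X).any(axis=1)
    Xfill = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    if use_kmeans and complete.sum() >= max(2 * K, K + 1):
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(X[complete])
        means = km.cluster_centers_.copy()
        weights = np.bincount(lab, minlength=K).astype(float)
        weights = np.maximum(weights, 1.0)
        weights /= weights.sum()
    else:
        gamma = rng.dirichlet(np.ones(K), size=n)
        weights = gamma.mean(axis=0)
        means = (gamma.T @ Xfill) / gamma.sum(axis=0)[:, None]
    base = np.cov(Xfill, rowvar=False)
    base = np.atleast_2d(base) + 1e-6 * np.eye(d) * max(np.trace(np.atleast_2d(base)) / d, 1e-12)
    covs = np.stack([base.copy() for _ in range(K)])
    return weights, means, covs


def _em_run(X, groups, weights, means, covs, tol, max_iter, ridge):
    trace = []
    prev = -np.inf
    converged = False
    gamma = None
    for _ in range(max_iter):
        logg, ll = _estep(X, groups, weights, means, covs)
        gamma = np.exp(logg)
        trace.append(ll)
        if prev > -np.inf and (ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        weights, means, covs = _mstep(X, groups, gamma, means, covs, ridge)
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()
    return weights, means, covs, np.asarray(trace), gamma, converged


def em_fit_missing(X, K: int, n_restarts: int = 10, tol: float = 1e-8,
                   max_iter: int = 500, ridge: float = 1e-6,
                   seed: int | None = None, init=None,
                   short_iter: int = 50) -> GmmModel:
    """Fit a K-component full-covariance mixture to data with NaN entries.

    Restarts follow the short-run strategy: every restart (the first
    k-means-initialized on complete rows, the rest from random
    responsibilities) runs for at most `short_iter` iterations, and the
    best by observed-data log-likelihood is then refined to convergence.
    `init=(weights, means, covs)` forces a single full run from explicit
    parameters.  Sets `converged=False` when the refined run hit
    `max_iter` without meeting the relative-loglik tolerance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, d = X.shape
    if K < 1 or n <= K:
        raise ValueError("need K >= 1 and more rows than components")
    groups = _pattern_groups(X)
    ss = np.random.SeedSequence(seed)
    starts = 1 if init is not None else max(1, n_restarts)
    cap = max_iter if (init is not None or starts == 1) else min(short_iter, max_iter)
    best = None
    for r, child in enumerate(ss.spawn(starts)):
        rng = np.random.default_rng(child)
        if init is not None:
            w0, m0, c0 = (np.asarray(a, dtype=float).copy() for a in init)
        else:
            w0, m0, c0 = _init_params(X, K, rng, use_kmeans=(r == 0))
        try:
            fit = _em_run(X, groups, w0, m0, c0, tol, cap, ridge)
        except np.linalg.LinAlgError:
            continue
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    if best is None:
        raise RuntimeError("all EM restarts failed")
    weights, means, covs, trace, gamma, converged = best
    if not converged and cap < max_iter:
        try:
            weights, means, covs, tail, gamma, converged = _em_run(
                X, groups, weights, means, covs, tol, max_iter - cap, ridge)
            trace = np.concatenate([trace, tail])
        except np.linalg.LinAlgError:
            pass
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    model = GmmModel(
        weights=weights, means=means, covariances=covs, loglik_trace=trace,
        responsibilities=gamma, labels=np.argmax(gamma, axis=1),
        n_params=n_free_params(K, d), converged=converged,
        settings=dict(K=K, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
                      ridge=ridge, seed=seed),
    )
    model.bic = bic_score(model, X)
    return model


def bic_score(model: GmmModel, X) -> float:
    """BIC = -2 loglik + p ln(n); smaller is better."""
    n = np.asarray(X).shape[0]
    return -2.0 * model.loglik + model.n_params * np.log(n)


def select_k(X, k_range=range(1, 6), seed: int | None = None,
             **em_kwargs):
    """Fit every K in `k_range` and pick the BIC minimizer.

    Returns (best_k, models_by_k, bic_table).
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    models: dict[int, GmmModel] = {}
    rows = []
    for K, child in zip(ks, children):
        try:
            model = em_fit_missing(X, K, seed=int(child.generate_state(1)[0] % (2**31)),
                                   **em_kwargs)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"K={K} skipped: {exc}")
            continue
        models[K] = model
        rows.append(dict(K=K, loglik=model.loglik, n_params=model.n_params,
                         bic=model.bic, converged=model.converged))
    if not models:
        raise RuntimeError("no mixture order could be fitted")
    table = pd.DataFrame(rows).set_index("K")
    best_k = int(table["bic"].idxmin())
    return best_k, models, table


def assign_labels(model: GmmModel):
    """Label the two components low/high by the sum of their mean vectors.

    Returns a dict with per-row labels, posterior probability of 'low',
    the mixing-weight share of the low component and the hard-assignment
    share.  For K != 2 the raw component indices are returned instead.
    """
    if model.K != 2:
        return dict(labels=model.labels, posterior=None,
                    mixing_share=None, hard_share=None)
    sums = model.means.sum(axis=1)
    low = int(np.argmin(sums))  # tie -> lowest component index
    label_names = np.where(model.labels == low, "low", "high")
    posterior_low = model.responsibilities[:, low]
    return dict(
        labels=label_names,
        posterior=posterior_low,
        low_component=low,
        mixing_share=float(model.weights[low]),
        hard_share=float(np.mean(model.labels == low)),
    )
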