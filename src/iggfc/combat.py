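"""Parametric empirical-Bayes batch correction (ComBat location/scale model).

Features are standardized by their grand mean and pooled (post-batch-fit)
variance; per-batch location and scale are estimated and shrunk toward
common priors — normal on locations, inverse-gamma on scales, hyperpriors by
method of moments — via the standard fixed-point iteration; the shrunken
effects are then removed and the grand scale restored.  Batches are the
96-well measurement plates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BatchModel:
    batches: list
    grand_mean: np.ndarray       # per feature
    pooled_var: np.ndarray       # per feature
    gamma_hat: np.ndarray        # batches x features, raw locations
    delta_hat: np.ndarray        # batches x features, raw scales
    gamma_star: np.ndarray       # EB-shrunken locations
    delta_star: np.ndarray       # EB-shrunken scales (> 0)
    n_iterations: int = 0


def _eb_fixed_point(g_hat, d_hat, g_bar, t2, a_prior, b_prior, n,
                    tol=1e-6, max_iter=500):
    """Iterate the parametric EB updates for one batch (vector over features)."""
    g_new, d_new = g_hat.copy(), d_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_old, d_old = g_new, d_new
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        # sum of squares about gamma_new: (n-1)*s^2 + n*(batch mean - gamma_new)^2
        ssq = (n - 1) * d_hat + n * (g_hat - g_new) ** 2
        d_new = (b_prior + 0.5 * ssq) / (n / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                     np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)))
        if change < tol:
            break
    return g_new, d_new, it


def combat_adjust(data: pd.DataFrame, batches,
                  tol: float = 1e-6, max_iter: int = 500
                  ) -> tuple[pd.DataFrame, BatchModel]:
    """Remove plate batch effects from a samples-x-features matrix.

    Parameters
    ----------
    data : DataFrame
        Samples in rows, features in columns (numeric).
    batches : array-like
        Batch (plate) label per sample.

    Returns the adjusted matrix (same index/columns) and the fitted
    :class:`BatchModel`.  Raises for a batch with fewer than 2 samples.
    """
    X = data.to_numpy(dtype=float)
    batches = np.asarray(batches)
    if batches.shape[0] != X.shape[0]:
        raise ValueError("one batch label per sample required")
    labels = [b for b in pd.unique(batches)]
    groups = [np.flatnonzero(batches == b) for b in labels]
    sizes = np.array([g.size for g in groups])
    if np.any(sizes < 2):
        bad = labels[int(np.argmin(sizes))]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples; "
                         "scale is undefined")
    n_samples, n_features = X.shape
    if len(labels) == 1:
        # nothing to remove: a single batch defines the grand distribution
        model = BatchModel(batches=labels, grand_mean=X.mean(axis=0),
                           pooled_var=X.var(axis=0),
                           gamma_hat=np.zeros((1, n_features)),
                           delta_hat=np.ones((1, n_features)),
                           gamma_star=np.zeros((1, n_features)),
                           delta_star=np.ones((1, n_features)))
        return data.astype(float).copy(), model

    # grand mean = size-weighted mean of batch means; pooled variance from
    # residuals about the batch means
    batch_means = np.vstack([X[g].mean(axis=0) for g in groups])
    grand_mean = (sizes[:, None] * batch_means).sum(axis=0) / n_samples
    resid = X.copy()
    for g, bm in zip(groups, batch_means):
        resid[g] -= bm
    pooled_var = (resid ** 2).sum(axis=0) / n_samples
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)

    Z = (X - grand_mean) / np.sqrt(pooled_var)
    gamma_hat = np.vstack([Z[g].mean(axis=0) for g in groups])
    delta_hat = np.vstack([Z[g].var(axis=0, ddof=1) for g in groups])
    delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

    if n_features < 2:
        warnings.warn("fewer than 2 features: empirical-Bayes shrinkage "
                      "skipped (priors undefined); using per-batch estimates")
        gamma_star, delta_star, iters = gamma_hat, delta_hat, 0
    else:
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        t2 = np.where(t2 <= 0, 1e-12, t2)
        # inverse-gamma hyperpriors by method of moments on delta_hat
        d_mean = delta_hat.mean(axis=1)
        d_var = delta_hat.var(axis=1, ddof=1)
        d_var = np.where(d_var <= 0, 1e-12, d_var)
        a_prior = (2 * d_var + d_mean ** 2) / d_var
        b_prior = (d_mean * d_var + d_mean ** 3) / d_var
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        iters = 0
        for i, g in enumerate(groups):
            gs, ds, it = _eb_fixed_point(
                gamma_hat[i], delta_hat[i], gamma_bar[i], t2[i],
                a_prior[i], b_prior[i], g.size, tol=tol, max_iter=max_iter)
            gamma_star[i], delta_star[i] = gs, ds
            iters = max(iters, it)
        delta_star = np.where(delta_star <= 0, 1e-12, delta_star)

    Z_adj = Z.copy()
    for i, g in enumerate(groups):
        Z_adj[g] = (Z[g] - gamma_star[i]) / np.sqrt(delta_star[i])
    out = Z_adj * np.sqrt(pooled_var) + grand_mean
    model = BatchModel(batches=labels, grand_mean=grand_mean,
                       pooled_var=pooled_var, gamma_hat=gamma_hat,
                       delta_hat=delta_hat, gamma_star=gamma_star,
                       delta_star=delta_star, n_iterations=iters)
    return pd.DataFrame(out, index=data.index, columns=data.columns), model
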