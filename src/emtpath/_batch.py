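"""Empirical-Bayes location/scale batch adjustment for dense matrices.

Parametric shrinkage of per-batch gene means and variances toward
common priors (normal prior on the location, inverse-gamma on the
scale), the standard empirical-Bayes batch-correction model.  Input is
samples x features; batches with a single sample are centered only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ss, n, a, b):
    return (0.5 * ss + b) / (n / 2.0 + a - 1.0)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=200):
    """Iterative solution of the EB posterior for one batch."""
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ss = ((z - g_new) ** 2).sum(axis=0)
        d_new = _postvar(ss, n, a, b)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var()
    return (2 * s2 + m**2) / max(s2, 1e-12)


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var()
    return (m * s2 + m**3) / max(s2, 1e-12)


def combat_adjust(data: pd.DataFrame, batch) -> pd.DataFrame:
    """Remove additive and multiplicative batch effects from *data*.

    *data* is samples x features, *batch* a per-sample label sequence.
    Returns the adjusted matrix with the same index/columns.
    """
    X = data.to_numpy(dtype=float)
    batch = np.asarray(batch)
    levels = pd.unique(batch)
    if len(levels) < 2:
        return data.copy()
    n, g = X.shape
    masks = [batch == b for b in levels]
    n_b = np.array([m.sum() for m in masks], dtype=float)

    batch_means = np.vstack([X[m].mean(axis=0) for m in masks])
    grand_mean = (n_b[:, None] * batch_means).sum(axis=0) / n
    fitted = np.zeros_like(X)
    for i, m in enumerate(masks):
        fitted[m] = batch_means[i]
    var_pooled = ((X - fitted) ** 2).sum(axis=0) / n
    var_pooled = np.maximum(var_pooled, 1e-12)

    z = (X - grand_mean) / np.sqrt(var_pooled)
    out = np.empty_like(z)
    for i, m in enumerate(masks):
        zb = z[m]
        g_hat = zb.mean(axis=0)
        if zb.shape[0] < 2:
            out[m] = zb - g_hat
            continue
        d_hat = zb.var(axis=0, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = g_hat.mean(), max(g_hat.var(), 1e-12)
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b)
        out[m] = (zb - g_star) / np.sqrt(np.maximum(d_star, 1e-12))
    adj = out * np.sqrt(var_pooled) + grand_mean
    return pd.DataFrame(adj, index=data.index, columns=data.columns)
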