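"""Shared least-squares primitives used by several stages.

Everything here is plain closed-form OLS algebra on numpy arrays; the heavier
statsmodels machinery is reserved for the phenotype-adjustment fits where a
full regression summary is useful.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["ols_rss", "gaussian_ml_loglik", "residualize", "slope_test"]


def ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Fit y = X b by least squares; return (b, rss, rank)."""
    b, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    return b, float(resid @ resid), int(rank)


def gaussian_ml_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood at the ML variance estimate sigma^2 = rss/n."""
    if rss <= 0 or n <= 0:
        raise ValueError("degenerate fit: zero residual sum of squares")
    sigma2 = rss / n
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def residualize(v: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Project v onto the orthogonal complement of the column space of W."""
    Q, _ = np.linalg.qr(W)
    return v - Q @ (Q.T @ v)


def slope_test(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of ``y`` on intercept + ``X[:, j]``.

    Columns of X may contain NaN; each test uses that column's complete
    observations (pairwise-complete deletion). Zero-variance columns get
    beta = nan, p = 1 (the caller decides whether to warn).

    Returns (beta, se, p, minus_log10_p, n_used) arrays, one entry per column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_col = X.shape[1]
    beta = np.full(n_col, np.nan)
    se = np.full(n_col, np.nan)
    p = np.ones(n_col)
    mlog10p = np.zeros(n_col)
    n_used = np.zeros(n_col, dtype=int)

    finite = np.isfinite(X)
    complete = finite.all(axis=0)

    def _fill(j_idx, xs, ys, ns):
        """Vectorised slope t-test for a block sharing the same sample mask."""
        xm = xs.mean(axis=0)
        ym = ys.mean(axis=0) if ys.ndim > 1 else ys.mean()
        xc = xs - xm
        yc = ys - ym
        sxx = (xc * xc).sum(axis=0)
        sxy = (xc * yc).sum(axis=0)
        syy = (yc * yc).sum(axis=0) if yc.ndim > 1 else float(yc @ yc)
        ok = sxx > 0
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        rss = syy - b * sxy
        rss = np.maximum(rss, 0.0)
        dof = ns - 2
        s2 = rss / np.maximum(dof, 1)
        s_err = np.sqrt(np.where(ok, s2 / np.where(ok, sxx, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s_err
        logsf = stats.t.logsf(np.abs(t), dof)
        pj = np.where(ok, 2.0 * np.exp(logsf), 1.0)
        pj = np.clip(pj, np.finfo(float).tiny, 1.0)
        mlj = np.where(ok, -(np.log(2.0) + logsf) / np.log(10.0), 0.0)
        beta[j_idx] = b
        se[j_idx] = s_err
        p[j_idx] = pj
        mlog10p[j_idx] = np.maximum(mlj, 0.0)
        n_used[j_idx] = ns

    if complete.any():
        idx = np.where(complete)[0]
        _fill(idx, X[:, idx], y[:, None] * np.ones(len(idx)), np.full(len(idx), len(y)))
    for j in np.where(~complete)[0]:
        m = finite[:, j]
        nj = int(m.sum())
        if nj < 3:
            n_used[j] = nj
            continue
        _fill(np.array([j]), X[m, j][:, None], y[m][:, None], np.array([nj]))
    return beta, se, p, mlog10p, n_used
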