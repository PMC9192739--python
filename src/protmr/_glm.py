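"""Fast per-variant regression primitives shared by the scan modules.

The linear scan uses Frisch-Waugh residualization (exactly equivalent to a
full OLS fit per variant, including the residual-variance degrees of
freedom), the logistic scan a small Newton-Raphson IRLS solved to machine
tolerance so that estimates and observed-information standard errors agree
with a full maximum-likelihood fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["linear_scan", "logit_fit", "logistic_scan"]


def linear_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Per-column OLS of ``y`` on each column of ``G`` plus covariates ``C``.

    Parameters
    ----------
    G : (n, m) dosage matrix.
    y : (n,) trait vector.
    C : (n, k) covariate design, must include the intercept column.

    Returns
    -------
    beta, se, p : (m,) arrays; ``monomorphic`` boolean mask. Flagged columns
    carry NaN estimates rather than being dropped.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    mono = G.std(axis=0) == 0.0
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    sgg = np.einsum("ij,ij->j", G_r, G_r)
    bad = mono | (sgg <= n * np.finfo(float).eps * max(1.0, float(np.max(sgg, initial=1.0))))
    sgg_safe = np.where(bad, 1.0, sgg)
    beta = (G_r.T @ y_r) / sgg_safe
    dof = n - C.shape[1] - 1
    rss = float(y_r @ y_r) - beta**2 * sgg_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sgg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p, bad


def logit_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 60):
    """Newton-Raphson logistic regression with step halving.

    Returns ``(beta, se, converged)`` where ``se`` comes from the inverse
    observed information at the optimum (the same covariance a statsmodels
    ``Logit`` fit reports).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    # intercept warm start
    pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar)) if np.allclose(X[:, 0], 1.0) else 0.0
    converged = False
    H = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step halving on the log-likelihood
        with np.errstate(over="ignore"):
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            with np.errstate(over="ignore"):
                ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-14:
                break
            scale *= 0.5
        beta = beta + scale * step
        # relative parameter-change criterion: robust to the floating-point
        # noise floor of the score with uncentered covariate columns
        if np.max(np.abs(scale * step) / (1.0 + np.abs(beta))) < tol * 100:
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return beta, se, converged


def logistic_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Per-column logistic regression of binary ``y`` on dosage + covariates.

    Returns ``(beta, se, p, monomorphic, converged)`` for the dosage term.
    P-values use the Wald z statistic (the logistic-regression convention).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    mono = G.std(axis=0) == 0.0
    for j in range(m):
        if mono[j]:
            continue
        X = np.column_stack([C, G[:, j]])
        b, s, ok = logit_fit(X, y)
        conv[j] = ok
        if ok and np.isfinite(s[-1]) and s[-1] > 0:
            beta[j] = b[-1]
            se[j] = s[-1]
            p[j] = 2.0 * stats.norm.sf(abs(b[-1] / s[-1]))
    return beta, se, p, mono, conv
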