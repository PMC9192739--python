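"""L1-penalized logistic regression with per-feature penalty factors.

IRLS with cyclic coordinate descent and warm-started lambda paths (the
glmnet algorithm), compiled with numba. Penalty factors of zero leave a
feature unpenalized, which is how covariates such as age and sex stay in
every model. Columns are standardized internally; coefficients are
returned on the original scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lasso_logistic_path", "make_lambda_path", "cv_deviance"]


@njit(cache=True)
def _soft(u: float, t: float) -> float:
    if u > t:
        return u - t
    if u < -t:
        return u + t
    return 0.0


@njit(cache=True)
def _cd_fit(X, y, lam, pf, beta, b0, max_outer=50, max_inner=200, tol=1e-7):
    """One penalized fit at penalty ``lam`` (features pre-standardized).

    Minimizes -loglik/n + lam * sum(pf_j * |beta_j|) by IRLS outer steps
    and coordinate descent on the weighted least-squares subproblem.
    Updates ``beta`` and returns (beta, b0).
    """
    n, p = X.shape
    for _ in range(max_outer):
        beta_old = beta.copy()
        b0_old = b0
        eta = b0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < 1e-5:
                w[i] = 1e-5
        z = eta + (y - mu) / w
        r = z - eta  # working residual
        wsum = w.sum()
        wx2 = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wx2[j] = s / n
        for _ in range(max_inner):
            dmax = 0.0
            # intercept
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            d0 = num / wsum
            if d0 != 0.0:
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > dmax:
                    dmax = abs(d0)
            for j in range(p):
                if wx2[j] <= 0.0:  # constant column can never enter
                    continue
                bj = beta[j]
                num = 0.0
                for i in range(n):
                    num += w[i] * X[i, j] * r[i]
                u = num / n + wx2[j] * bj
                bnew = _soft(u, lam * pf[j]) / wx2[j]
                d = bnew - bj
                if d != 0.0:
                    beta[j] = bnew
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    if abs(d) > dmax:
                        dmax = abs(d)
            if dmax < tol:
                break
        delta_outer = abs(b0 - b0_old)
        for j in range(p):
            d = abs(beta[j] - beta_old[j])
            if d > delta_outer:
                delta_outer = d
        if delta_outer < tol:
            break
    return beta, b0


@njit(cache=True)
def _path_fit(X, y, lambdas, pf):
    """Warm-started coefficient path; returns (B [n_lam, p], b0s [n_lam])."""
    n, p = X.shape
    B = np.zeros((lambdas.shape[0], p))
    b0s = np.zeros(lambdas.shape[0])
    beta = np.zeros(p)
    pbar = y.mean()
    if pbar < 1e-6:
        pbar = 1e-6
    if pbar > 1.0 - 1e-6:
        pbar = 1.0 - 1e-6
    b0 = np.log(pbar / (1.0 - pbar))
    for k in range(lambdas.shape[0]):
        beta, b0 = _cd_fit(X, y, lambdas[k], pf, beta, b0)
        B[k] = beta
        b0s[k] = b0
    return B, b0s


def make_lambda_path(X: np.ndarray, y: np.ndarray, pf: np.ndarray,
                     n_lambda: int = 30,
                     lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from the smallest lambda zeroing every
    penalized coefficient down to ``lambda_min_ratio`` times it."""
    n = len(y)
    Z, _, _, _ = _standardize(np.asarray(X, dtype=float))
    resid = y - y.mean()
    grad = np.abs(Z.T @ resid) / n
    pen = pf > 0
    if not pen.any():
        return np.array([0.0])
    lam_max = float(np.max(grad[pen] / pf[pen])) * 1.001
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, sd == 0] = 0.0  # constant feature can never enter the model
    return Z, mean, sd_safe, sd == 0


def lasso_logistic_path(X: np.ndarray, y: np.ndarray, pf: np.ndarray,
                        lambdas: np.ndarray):
    """Fit the penalized path; returns coefficients on the original scale.

    Output: ``(B, b0)`` with ``B`` of shape (n_lambda, p).
    """
    Z, mean, sd, const = _standardize(np.asarray(X, dtype=float))
    B, b0s = _path_fit(np.ascontiguousarray(Z), np.asarray(y, dtype=float),
                       np.asarray(lambdas, dtype=float),
                       np.asarray(pf, dtype=float))
    B_orig = B / sd
    B_orig[:, const] = 0.0
    b0_orig = b0s - B_orig @ mean
    return B_orig, b0_orig


def cv_deviance(X: np.ndarray, y: np.ndarray, pf: np.ndarray,
                lambdas: np.ndarray, folds) -> tuple[np.ndarray, np.ndarray]:
    """Mean held-out binomial deviance per lambda and its standard error
    across folds. ``folds`` is an iterable of (train_idx, test_idx)."""
    dev = []
    for tr, te in folds:
        B, b0 = lasso_logistic_path(X[tr], y[tr], pf, lambdas)
        eta = b0[:, None] + B @ X[te].T           # (n_lam, n_te)
        yt = y[te][None, :]
        ll = yt * eta - np.logaddexp(0.0, eta)
        dev.append(-2.0 * ll.mean(axis=1))
    dev = np.vstack(dev)
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
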