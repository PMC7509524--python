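"""Newton-Raphson logistic solver for resampling hot loops.

All reported model fits in this package go through statsmodels.  This solver
exists only so that bootstrap refits (thousands per analysis) are cheap: warm
started from the full-data estimate they converge in two or three Newton
steps.  It is cross-validated against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass
class LogitFit:
    params: np.ndarray
    llf: float
    cov: np.ndarray | None
    converged: bool


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), stable for large |eta|
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogitFit:
    """Maximum-likelihood logistic regression with step-halving Newton updates.

    ``X`` must already include any intercept column.  Returns a non-converged
    ``LogitFit`` (never raises) on singular information matrices so that
    resampling loops can count failures and move on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)

    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    H = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return LogitFit(beta, ll, None, False)
        # step-halving to guarantee monotone log-likelihood
        factor = 1.0
        for _ in range(25):
            cand = beta + factor * step
            eta_cand = X @ cand
            ll_cand = _loglik(eta_cand, y)
            if ll_cand >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            return LogitFit(beta, ll, None, False)
        beta, eta = cand, eta_cand
        if not np.all(np.isfinite(beta)):
            return LogitFit(beta, ll_cand, None, False)
        if abs(ll_cand - ll) < tol * (abs(ll) + 1.0) and np.max(np.abs(step)) < 1e-6:
            ll = ll_cand
            converged = True
            break
        ll = ll_cand

    cov = None
    if converged and H is not None:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return LogitFit(beta, ll, cov, converged)
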