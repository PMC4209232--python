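"""Fast Newton–Raphson (IRLS) logistic regression with Wald and Rao score
tests.

This is the numerical core used by the bootstrap stepwise machinery, which
needs tens of thousands of small maximum-likelihood fits; it matches
``statsmodels.Logit`` coefficients and standard errors to machine precision
(verified in the test suite). Separation and non-convergence are reported as
a flag on the result, never as an exception, so resampling loops can skip
degenerate replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: |coefficient| above which a fit is declared (quasi-)separated.
_SEPARATION_BOUND = 30.0


@dataclass
class GlmFit:
    """Result of one logistic maximum-likelihood fit."""

    beta: np.ndarray
    cov: np.ndarray | None
    converged: bool
    n_iter: int
    loglik: float
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full_like(self.beta, np.nan)
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.X if X is None else X
        return _expit(X @ self.beta)


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable form
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: np.ndarray | float | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> GlmFit:
    """Fit a logistic model by Newton–Raphson with optional quadratic penalty.

    Parameters
    ----------
    X : (n, p) design matrix (the caller supplies any intercept column).
    y : (n,) binary outcome.
    ridge : per-coefficient L2 penalty weights (scalar or length-p vector);
        ``None`` or 0 gives plain maximum likelihood. The penalised score is
        ``X'(y - p) - ridge * beta``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ridge is None:
        pen = np.zeros(p)
    else:
        pen = np.broadcast_to(np.asarray(ridge, dtype=float), (p,)).copy()
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    converged = False
    halvings_budget = 20
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return GlmFit(beta, None, False, it, _loglik(y, eta), X, y)
        # step-halving keeps the (penalised) log-likelihood non-decreasing
        ll_cur = _loglik(y, eta) - 0.5 * float(pen @ beta**2)
        new_beta = beta + step
        for _ in range(halvings_budget):
            eta_new = X @ new_beta
            ll_new = _loglik(y, eta_new) - 0.5 * float(pen @ new_beta**2)
            if np.isfinite(ll_new) and ll_new >= ll_cur - 1e-12:
                break
            new_beta = beta + 0.5 * (new_beta - beta)
        beta = new_beta
        if np.max(np.abs(step)) < tol or abs(ll_new - ll_old) < 1e-13 * (1 + abs(ll_new)):
            converged = True
            break
        ll_old = ll_new

    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        converged = False
    eta = X @ beta
    mu = _expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    H[np.diag_indices_from(H)] += pen
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov, converged = None, False
    return GlmFit(beta, cov, converged, it, _loglik(y, eta), X, y)


def score_test(fit: GlmFit, Z: np.ndarray) -> tuple[float, float]:
    """Rao score test for adding columns ``Z`` to a fitted model.

    Evaluated at the current fit (candidate coefficients fixed at zero); this
    is the entry test of classical stepwise selection. Returns
    ``(chi2, p-value)`` with ``df = Z.shape[1]``.
    """
    X, y = fit.X, fit.y
    mu = fit.predict()
    w = mu * (1.0 - mu)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    U = Z.T @ (y - mu)                          # score for the new columns
    # efficient information of Z adjusted for X:
    ZtWZ = (Z * w[:, None]).T @ Z
    ZtWX = (Z * w[:, None]).T @ X
    XtWX = (X * w[:, None]).T @ X
    try:
        V = ZtWZ - ZtWX @ np.linalg.solve(XtWX, ZtWX.T)
        chi2 = float(U @ np.linalg.solve(V, U))
    except np.linalg.LinAlgError:
        return np.nan, 1.0
    if not np.isfinite(chi2) or chi2 < 0:
        return np.nan, 1.0
    df = Z.shape[1]
    return chi2, float(stats.chi2.sf(chi2, df))


def wald_block_test(fit: GlmFit, idx: np.ndarray) -> tuple[float, float]:
    """Wald chi-square test that a block of coefficients is zero."""
    if fit.cov is None:
        return np.nan, 1.0
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return np.nan, 1.0
    return chi2, float(stats.chi2.sf(chi2, len(idx)))
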