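"""Logistic-regression engines shared by the burden, single-variant, and
window tests.

Three routes are provided:

* ``wald_logistic`` — maximum-likelihood fit (statsmodels) with a two-sided
  Wald p-value on one focal column; used for category and gene tests.
* ``firth_logistic`` — Jeffreys-prior penalised fit, used as a fallback when
  the ML fit separates or fails to converge (rare-variant burdens with
  unbalanced outcomes can separate).
* ``score_scan`` — Rao score tests of many focal columns against one shared
  null fit; algebraically vectorised, used for genome-wide scans where a
  per-column ML fit would be needlessly slow.  Under the null the score and
  Wald statistics are asymptotically identical.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats

__all__ = ["wald_logistic", "firth_logistic", "score_scan", "NullModel", "fit_null"]

_MAX_ABS_COEF = 15.0  # |log-OR| beyond this is treated as separation


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = x.shape[0]
    cols = [np.ones(n), x]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    return np.column_stack(cols)


def wald_logistic(x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None):
    """ML logistic fit of ``y ~ x + covariates``; Wald test on ``x``.

    Returns ``(estimate, p, flag)``; on separation or non-convergence the
    Firth-penalised fit is used and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0:
        return 0.0, 1.0, "degenerate"
    X = _design(x, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta = fit.params[1]
        se = fit.bse[1]
        ok = (
            fit.mle_retvals.get("converged", False)
            and np.isfinite(se)
            and abs(beta) < _MAX_ABS_COEF
        )
    except Exception:
        ok = False
    if not ok:
        beta, se = firth_logistic(X, y)
        if not np.isfinite(se[1]) or se[1] == 0:
            return 0.0, 1.0, "degenerate"
        z = beta[1] / se[1]
        return float(beta[1]), float(2 * stats.norm.sf(abs(z))), "firth"
    z = beta / se
    return float(beta), float(2 * stats.norm.sf(abs(z))), ""


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior bias reduction).

    Returns ``(beta, se)`` arrays over all columns of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat-matrix diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X, info_inv, XtW.T)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # dampen runaway steps
        if np.max(np.abs(step)) > 5:
            step = step * (5 / np.max(np.abs(step)))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se


class NullModel:
    """Fitted covariate-only logistic null for score scanning."""

    def __init__(self, X: np.ndarray, y: np.ndarray, p_hat: np.ndarray):
        self.X = X
        self.y = y
        self.p_hat = p_hat
        self.w = p_hat * (1 - p_hat)
        self.resid = y - p_hat
        XtW = X.T * self.w
        self.info_inv = np.linalg.pinv(XtW @ X)
        self.eta = np.log(p_hat / (1 - p_hat))


def fit_null(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Fit the covariate-only logistic null model once for a scan."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is not None and covariates.size:
        X = np.column_stack([np.ones(n), covariates])
    else:
        X = np.ones((n, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    p_hat = np.clip(fit.predict(X), 1e-10, 1 - 1e-10)
    return NullModel(X, y, p_hat)


def score_scan(null: NullModel, G, outcomes: np.ndarray | None = None):
    """Rao score tests of each column of ``G`` against the fitted null.

    ``G`` may be dense or scipy-sparse, shape (n_samples, m).  When
    ``outcomes`` (n_samples, r) is given, the numerator is recomputed for
    each outcome column against the same plugged-in null weights (used by
    the permutation calibration); otherwise the null's own outcome is used.

    Returns ``(chi2, p, sign)`` with shape (m,) — or (m, r) for chi2/p when
    multiple outcomes are supplied.
    """
    X, w, info_inv = null.X, null.w, null.info_inv
    if sp.issparse(G):
        Gw = G.multiply(w[:, None]).tocsc()
        A = np.asarray((Gw.T @ X).T)  # (k, m)
        gtwg = np.asarray(G.multiply(Gw).sum(axis=0)).ravel()
    else:
        G = np.asarray(G, dtype=float)
        Gw = G * w[:, None]
        A = X.T @ Gw  # (k, m)
        gtwg = np.einsum("ij,ij->j", G, Gw)
    V = gtwg - np.einsum("km,kl,lm->m", A, null.info_inv, A)
    V = np.clip(V, 0, None)
    if outcomes is None:
        U = np.asarray(G.T @ null.resid).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(V > 0, U * U / np.maximum(V, 1e-300), 0.0)
        p = stats.chi2.sf(chi2, 1)
        p = np.where(V > 0, p, 1.0)
        return chi2, p, np.sign(U).astype(int)
    R = outcomes - null.p_hat[:, None]
    U = np.asarray(G.T @ R)  # (m, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V[:, None] > 0, U * U / np.maximum(V[:, None], 1e-300), 0.0)
    p = stats.chi2.sf(chi2, 1)
    return chi2, p, np.sign(U).astype(int)
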