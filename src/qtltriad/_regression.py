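"""Shared least-squares helpers.

Thin numpy/scipy OLS core used by the QTL scan and the conditional-regression
mediation tests, where per-fit overhead matters (tens of thousands of small
fits per run). Estimates are ordinary least squares; p-values come from the
t distribution with residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OlsFit", "ols_fit", "add_intercept", "residualize"]


@dataclass(frozen=True)
class OlsFit:
    """Coefficients and inference for one least-squares fit."""

    beta: np.ndarray          # coefficient per design column
    se: np.ndarray            # standard error per coefficient
    t_stat: np.ndarray
    p: np.ndarray             # two-sided, t distribution on df_resid
    df_resid: int
    rank: int
    rss: float
    fitted: np.ndarray
    resid: np.ndarray

    @property
    def ok(self) -> bool:
        """True when the design had full column rank and positive df."""
        return self.rank == len(self.beta) and self.df_resid > 0


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    """Prepend a column of ones; with X=None return just the intercept."""
    ones = np.ones((n, 1))
    if X is None or X.size == 0:
        return ones
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([ones, X])


def ols_fit(y: np.ndarray, X: np.ndarray) -> OlsFit:
    """OLS of y on the columns of X (X must already contain any intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - rank
    if rank < k or df <= 0:
        nan = np.full(k, np.nan)
        return OlsFit(beta, nan, nan, nan, df, rank, rss, fitted, resid)
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    # exactly collinear y gives rss == 0; report p as 0 rather than nan
    p = np.where(np.isfinite(t_stat), p, 0.0)
    return OlsFit(beta, se, t_stat, p, df, rank, rss, fitted, resid)


def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y after projecting out the column space of X."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
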