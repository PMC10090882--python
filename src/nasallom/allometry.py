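"""Allometric line fitting: OLS, standardized major axis (SMA/RMA) and PGLS.

All fits operate on log10-transformed size variables, the conventional axes
for allometry, so slopes are dimensionless scaling exponents and intercepts
are in log10 units of the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "AllometricFit",
    "NonPositiveValueError",
    "SingularCovarianceError",
    "ZeroVarianceError",
    "fit_ols",
    "fit_pgls",
    "fit_sma",
    "log_transform",
]


class ZeroVarianceError(ValueError):
    """A regressor (or, for SMA, either axis) has zero variance."""


class NonPositiveValueError(ValueError):
    """A value to be log-transformed is zero or negative."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Phylogenetic covariance matrix is singular.

    Usually caused by zero-length terminal branches (identical tips); jitter
    them by a small fraction of the tree depth before inverting.
    """


@dataclass
class AllometricFit:
    """A fitted allometric line y = intercept + slope * x (log10–log10)."""

    method: str
    slope: float
    intercept: float
    n: int
    r2: float
    resid_var: float
    coef_cov: np.ndarray | None = None  # 2x2, order (intercept, slope)
    loglik: float | None = None

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    @property
    def slope_se(self) -> float | None:
        if self.coef_cov is None:
            return None
        return float(np.sqrt(self.coef_cov[1, 1]))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "r2": self.r2,
            "resid_var": self.resid_var,
            "loglik": self.loglik,
        }
        if self.coef_cov is not None:
            d["coef_cov"] = np.asarray(self.coef_cov).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricFit":
        cov = d.get("coef_cov")
        return cls(
            method=d["method"],
            slope=d["slope"],
            intercept=d["intercept"],
            n=d["n"],
            r2=d["r2"],
            resid_var=d["resid_var"],
            coef_cov=None if cov is None else np.asarray(cov, dtype=float),
            loglik=d.get("loglik"),
        )


def log_transform(records: pd.DataFrame, variables: Iterable[str]) -> pd.DataFrame:
    """Return a copy with the named columns replaced by their base-10 logs.

    Missing values pass through; zero or negative values raise
    :class:`NonPositiveValueError` naming the offending row.
    """
    out = records.copy()
    for var in variables:
        col = pd.to_numeric(out[var], errors="raise")
        bad = col.notna() & (col <= 0)
        if bad.any():
            idx = out.index[bad][0]
            raise NonPositiveValueError(
                f"cannot log-transform {var!r}: non-positive value "
                f"{col[idx]!r} in row {idx!r}"
            )
        out[var] = np.log10(col)
    return out


def _prepare_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def fit_ols(x, y) -> AllometricFit:
    """Ordinary least squares of y on x."""
    x, y = _prepare_xy(x, y)
    if np.ptp(x) == 0:
        raise ZeroVarianceError("x has zero variance")
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    sigma2 = rss / (n - 2)
    XtX_inv = np.linalg.inv(X.T @ X)
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return AllometricFit(
        method="ols",
        slope=float(beta[1]),
        intercept=float(beta[0]),
        n=n,
        r2=max(0.0, min(1.0, r2)),
        resid_var=sigma2,
        coef_cov=sigma2 * XtX_inv,
    )


def fit_sma(x, y) -> AllometricFit:
    """Standardized (reduced) major axis fit.

    slope = sign(r) * sd(y)/sd(x); the line passes through the bivariate
    mean.  The slope variance follows Warton et al.'s large-sample formula
    var(b) = b^2 (1 - r^2) / n.
    """
    x, y = _prepare_xy(x, y)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("SMA requires nonzero variance on both axes")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    n = x.size
    var_b = slope**2 * (1 - r**2) / n
    # intercept variance via delta method around (ybar, b)
    resid = y - (intercept + slope * x)
    var_a = resid.var(ddof=2) / n + x.mean() ** 2 * var_b
    cov = np.array([[var_a, 0.0], [0.0, var_b]])
    return AllometricFit(
        method="sma",
        slope=float(slope),
        intercept=intercept,
        n=n,
        r2=r**2,
        resid_var=float(resid.var(ddof=2)),
        coef_cov=cov,
    )


def cho_factor_jittered(C: np.ndarray):
    """Cholesky factor of C, adding a 1e-8 x depth diagonal jitter if needed.

    Near-singular phylogenetic covariances arise from (near-)zero-length
    terminal branches, i.e. effectively identical tips; the jitter is the
    standard remedy and is announced with a warning.  A matrix that stays
    indefinite even after jittering raises
    :class:`SingularCovarianceError`.
    """
    depth = float(np.max(np.diag(C)))
    try:
        cho = linalg.cho_factor(C, lower=True)
        # a numerically "successful" factorization of a singular matrix has
        # near-zero pivots, which would give absurd GLS weights
        if np.min(np.diag(cho[0])) ** 2 > 1e-10 * depth:
            return cho
    except np.linalg.LinAlgError:
        pass
    warnings.warn(
        "covariance matrix is numerically singular (zero-length terminal "
        f"branches?); jittering the diagonal by 1e-8 x {depth:g}",
        stacklevel=3,
    )
    try:
        return linalg.cho_factor(C + 1e-8 * depth * np.eye(C.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance matrix is singular or not positive definite even "
            "after diagonal jitter"
        ) from exc


def _solve_gls(X: np.ndarray, y: np.ndarray, C: np.ndarray):
    cho = cho_factor_jittered(C)
    Ci_X = linalg.cho_solve(cho, X)
    Ci_y = linalg.cho_solve(cho, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    resid = y - X @ beta
    Ci_r = linalg.cho_solve(cho, resid)
    rss = float(resid @ Ci_r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return beta, XtCiX, rss, logdet, cho


def fit_pgls(x, y, C: np.ndarray) -> AllometricFit:
    """Phylogenetic GLS under a Brownian-motion covariance matrix C.

    beta = (X' C^-1 X)^-1 X' C^-1 y with X = [1, x]; the residual scale is
    estimated as rss/(n - 2) (REML-style degrees of freedom) and the
    reported log-likelihood is the profile ML value.
    """
    x, y = _prepare_xy(x, y)
    C = np.asarray(C, dtype=float)
    n = x.size
    if C.shape != (n, n):
        raise ValueError(f"C must be {n}x{n}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    X = np.column_stack([np.ones(n), x])
    beta, XtCiX, rss, logdet, cho = _solve_gls(X, y, C)
    sigma2 = rss / (n - 2)
    coef_cov = sigma2 * np.linalg.inv(XtCiX)
    # GLS R^2 against the GLS-weighted mean
    ones = np.ones(n)
    Ci_1 = linalg.cho_solve(cho, ones)
    mu = float((Ci_1 @ y) / (Ci_1 @ ones))
    dev = y - mu
    tss = float(dev @ linalg.cho_solve(cho, dev))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return AllometricFit(
        method="pgls",
        slope=float(beta[1]),
        intercept=float(beta[0]),
        n=n,
        r2=max(0.0, min(1.0, r2)),
        resid_var=sigma2,
        coef_cov=coef_cov,
        loglik=float(loglik),
    )
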