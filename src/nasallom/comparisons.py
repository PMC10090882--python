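"""Endotherm-versus-ectotherm line comparisons.

The testing scheme is conditional: the two groups' slopes are compared
first; only when the slopes are statistically indistinguishable is the
intercept (elevation) difference tested at a common slope — an ANCOVA for
OLS, a phylogenetic ANCOVA (GLS with a group dummy) for PGLS, and a
Warton-style elevation test for SMA.  Testing intercepts under
heterogeneous slopes is meaningless, so :func:`compare_groups` records the
intercept as "not tested" in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .allometry import (
    AllometricFit,
    cho_factor_jittered,
    fit_ols,
    fit_pgls,
    fit_sma,
    log_transform,
)

__all__ = [
    "GroupComparisonResult",
    "SlopeHeterogeneityError",
    "compare_groups",
    "test_intercept_difference",
    "test_slope_difference",
]

METHODS = ("ols", "sma", "pgls")


class SlopeHeterogeneityError(RuntimeError):
    """Intercept test called although the slopes differ significantly."""


def _split_groups(x, y, group):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group).ravel()
    if not (x.size == y.size == group.size):
        raise ValueError("x, y and group must have equal length")
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    g = (group == levels[1]).astype(float)
    for lev in levels:
        if (group == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 observations")
    return x, y, g, levels


def _gls_wald(X, y, C, coef_index):
    """t statistic and p-value for one coefficient of a (G)LS fit."""
    n = X.shape[0]
    if C is None:
        cho = None
        XtCiX = X.T @ X
        beta = np.linalg.solve(XtCiX, X.T @ y)
        resid = y - X @ beta
        rss = float(resid @ resid)
    else:
        cho = cho_factor_jittered(np.asarray(C, dtype=float))
        CiX = linalg.cho_solve(cho, X)
        XtCiX = X.T @ CiX
        beta = np.linalg.solve(XtCiX, X.T @ linalg.cho_solve(cho, y))
        resid = y - X @ beta
        rss = float(resid @ linalg.cho_solve(cho, resid))
    if rss <= 1e-20 * max(1.0, float(y @ y)):
        # perfect fit: zero residual variance, so the coefficient is either
        # exactly null (identical lines) or different with certainty
        scale = max(1.0, float(np.max(np.abs(beta))))
        if abs(beta[coef_index]) <= 1e-8 * scale:
            return 0.0, 1.0
        return np.inf, 0.0
    df = n - X.shape[1]
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtCiX)
    t = float(beta[coef_index] / np.sqrt(cov[coef_index, coef_index]))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(p)


# ---------------------------------------------------------------------------
# SMA (Warton-style) common-slope and elevation machinery


def _sma_residual_fitted_corr(x, y, b):
    """Correlation of residual (y - b x) and fitted (y + b x) axes."""
    r = y - b * x
    f = y + b * x
    sr = r.std(ddof=1)
    sf = f.std(ddof=1)
    if sf == 0 or sr <= 1e-10 * sf:  # exact fit up to floating-point dust
        return 0.0
    return float(np.corrcoef(r, f)[0, 1])


def _sma_lr_stat(groups, b):
    """-2 log Lambda of a common SMA slope b across groups."""
    stat = 0.0
    for x, y in groups:
        r = _sma_residual_fitted_corr(x, y, b)
        r2 = min(r * r, 1 - 1e-12)
        stat += -(len(x) - 2) * np.log1p(-r2)
    return stat


def _sma_common_slope(groups):
    slopes = [fit_sma(x, y).slope for x, y in groups]
    lo = min(slopes)
    hi = max(slopes)
    span = max(abs(lo), abs(hi))
    res = optimize.minimize_scalar(
        lambda b: _sma_lr_stat(groups, b),
        bounds=(lo - 2 * span, hi + 2 * span),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # the group slopes themselves are candidate optima (and the exact
    # optimum when the groups share a noise-free line, where the smooth
    # search cannot land on the needle-shaped minimum)
    candidates = [float(res.x)] + slopes
    return min(candidates, key=lambda b: _sma_lr_stat(groups, b))


def _sma_slope_test(x, y, g, n_perm=None, rng=None):
    groups = [(x[g == 0], y[g == 0]), (x[g == 1], y[g == 1])]
    b_c = _sma_common_slope(groups)
    stat = _sma_lr_stat(groups, b_c)
    if n_perm:
        rng = np.random.default_rng(rng)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(g)
            pg = [(x[perm == 0], y[perm == 0]), (x[perm == 1], y[perm == 1])]
            ps = _sma_lr_stat(pg, _sma_common_slope(pg))
            if ps >= stat:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, b_c


def _sma_elevation_test(x, y, g):
    groups = [(x[g == 0], y[g == 0]), (x[g == 1], y[g == 1])]
    b_c = _sma_common_slope(groups)
    # curvature of the LR surface gives the common-slope variance
    h = 1e-4 * max(abs(b_c), 1.0)
    curv = (
        _sma_lr_stat(groups, b_c + h)
        - 2 * _sma_lr_stat(groups, b_c)
        + _sma_lr_stat(groups, b_c - h)
    ) / h**2
    var_b = 2.0 / curv if curv > 0 else np.inf
    (x0, y0), (x1, y1) = groups
    r0 = y0 - b_c * x0
    r1 = y1 - b_c * x1
    diff = r0.mean() - r1.mean()
    var = (
        r0.var(ddof=1) / len(r0)
        + r1.var(ddof=1) / len(r1)
        + (x0.mean() - x1.mean()) ** 2 * var_b
    )
    if var == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
    stat = diff**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------


def test_slope_difference(x, y, group, method="ols", C=None, n_perm=None, rng=None):
    """Test equality of the two groups' allometric slopes.

    OLS/PGLS: Wald t test on the group-by-x interaction in the pooled
    (generalized) least-squares model.  SMA: likelihood-ratio common-slope
    test against chi-square(1), with an optional seeded permutation p-value
    (``n_perm``).  Returns ``(statistic, p_value)``.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    x, y, g, _ = _split_groups(x, y, group)
    if method == "sma":
        stat, p, _ = _sma_slope_test(x, y, g, n_perm=n_perm, rng=rng)
        return stat, p
    X = np.column_stack([np.ones_like(x), x, g, g * x])
    if method == "ols":
        C = None
    elif C is None:
        raise ValueError("PGLS requires a covariance matrix C")
    return _gls_wald(X, y, C, coef_index=3)


def test_intercept_difference(x, y, group, method="ols", C=None):
    """Test the group intercept (elevation) difference at a common slope.

    The caller is responsible for having established slope homogeneity
    first (see :func:`compare_groups`).  OLS: classical ANCOVA F on the
    group term; PGLS: Wald test on the group dummy under the phylogenetic
    covariance (phylogenetic ANCOVA); SMA: elevation test at the common
    SMA slope.  Returns ``(statistic, p_value)``.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    x, y, g, _ = _split_groups(x, y, group)
    if method == "sma":
        return _sma_elevation_test(x, y, g)
    X = np.column_stack([np.ones_like(x), x, g])
    if method == "ols":
        t, p = _gls_wald(X, y, None, coef_index=2)
        return t * t, p  # ANCOVA F on 1 df
    if C is None:
        raise ValueError("PGLS requires a covariance matrix C")
    return _gls_wald(X, y, C, coef_index=2)


@dataclass
class GroupComparisonResult:
    """Outcome of one (size proxy x response x method) comparison cell."""

    comparison: str
    response: str
    method: str
    slope_stat: float
    slope_p: float
    intercept_tested: bool
    intercept_stat: float | None
    intercept_p: float | None
    alpha: float
    n_by_group: dict[str, int] = field(default_factory=dict)
    fits: dict[str, AllometricFit] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        """True when the cell reports any significant group difference."""
        if self.slope_p < self.alpha:
            return True
        return self.intercept_tested and self.intercept_p < self.alpha

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "response": self.response,
            "method": self.method,
            "slope_stat": self.slope_stat,
            "slope_p": self.slope_p,
            "intercept_tested": self.intercept_tested,
            "intercept_stat": self.intercept_stat,
            "intercept_p": self.intercept_p,
            "alpha": self.alpha,
            "n_by_group": dict(self.n_by_group),
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupComparisonResult":
        return cls(
            comparison=d["comparison"],
            response=d["response"],
            method=d["method"],
            slope_stat=d["slope_stat"],
            slope_p=d["slope_p"],
            intercept_tested=d["intercept_tested"],
            intercept_stat=d["intercept_stat"],
            intercept_p=d["intercept_p"],
            alpha=d["alpha"],
            n_by_group=dict(d.get("n_by_group", {})),
            fits={k: AllometricFit.from_dict(f) for k, f in d.get("fits", {}).items()},
        )


_FITTERS = {"ols": fit_ols, "sma": fit_sma}


def _fit_group(method, x, y, C, idx):
    if method == "pgls":
        return fit_pgls(x[idx], y[idx], C[np.ix_(idx, idx)])
    return _FITTERS[method](x[idx], y[idx])


def compare_groups(
    records: pd.DataFrame,
    size_var: str,
    response_var: str,
    method: str = "pgls",
    tree=None,
    C: np.ndarray | None = None,
    alpha: float = 0.05,
    group_var: str = "thermo_class",
    label_var: str | None = None,
    comparison: str | None = None,
) -> GroupComparisonResult:
    """Run the conditional slope-then-intercept comparison for one cell.

    Raw sizes are log10-transformed internally.  For PGLS either a
    pre-aligned covariance matrix *C* or a tree plus *label_var* (the
    column holding tip labels) must be given.  The intercept test runs only
    when the slope test is non-significant at *alpha*; otherwise the
    intercept fields record "not tested" (``intercept_tested=False``).
    """
    method = method.lower()
    data = log_transform(
        records.dropna(subset=[size_var, response_var]), [size_var, response_var]
    )
    x = data[size_var].to_numpy(dtype=float)
    y = data[response_var].to_numpy(dtype=float)
    group = data[group_var].to_numpy()
    if method == "pgls" and C is None:
        if tree is None:
            raise ValueError("PGLS requires a tree or a covariance matrix")
        from .phylo import bm_covariance

        labels = data[label_var if label_var else "species"].astype(str).tolist()
        C, _ = bm_covariance(tree, taxa=labels)
    x_, y_, g, levels = _split_groups(x, y, group)
    slope_stat, slope_p = test_slope_difference(x, y, group, method=method, C=C)
    if slope_p >= alpha:
        int_stat, int_p = test_intercept_difference(x, y, group, method=method, C=C)
        tested = True
    else:
        int_stat = int_p = None
        tested = False
    fits = {}
    for lev in levels:
        idx = np.flatnonzero(group == lev)
        fits[str(lev)] = _fit_group(method, x, y, C, idx)
    return GroupComparisonResult(
        comparison=comparison or size_var,
        response=response_var,
        method=method,
        slope_stat=slope_stat,
        slope_p=slope_p,
        intercept_tested=tested,
        intercept_stat=int_stat,
        intercept_p=int_p,
        alpha=alpha,
        n_by_group={str(lev): int((group == lev).sum()) for lev in levels},
        fits=fits,
    )
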