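"""Covariate-adjusted univariate inference.

Implements the analyses applied to the derived FA summaries and sleep
measures: a covariate-adjusted group F-test (nested-model comparison), partial
Pearson correlation with percentile-bootstrap confidence intervals,
Benjamini-Hochberg FDR over an analysis family, and percentile-bootstrap
simple mediation (indirect effect a*b).

Covariates default to the study's set: age, sex, absolute and relative motion
in scanner; any extra columns (medication flags, symptom totals) are passed
through the same design-matrix machinery.  Listwise exclusion of missing
values is the caller's responsibility and is enforced by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmResult",
    "PartialCorrelationResult",
    "MediationResult",
    "glm_group_test",
    "partial_correlation",
    "bh_fdr",
    "mediate",
    "correlation_family",
]

_MAX_REDRAW_FACTOR = 10  # cap on degenerate bootstrap redraws


def _design(cov: Optional[pd.DataFrame], n: int) -> np.ndarray:
    """Intercept-plus-covariates design matrix; validates for missingness."""
    if cov is None or (hasattr(cov, "shape") and cov.shape[-1] == 0):
        return np.ones((n, 1))
    arr = np.asarray(cov, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError("covariate rows do not match data length")
    if np.isnan(arr).any():
        raise ValueError("missing values among covariates; apply listwise exclusion first")
    return np.column_stack([np.ones(n), arr])


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns involved in the collinearity by leave-one-out rank
        full_rank = np.linalg.matrix_rank(X)
        involved = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {involved}")


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class GlmResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    adjusted_means: dict


def glm_group_test(y, group, cov: Optional[pd.DataFrame] = None) -> GlmResult:
    """F-test for a binary group factor adjusting for covariates.

    Compares the residual sum of squares of the full model
    ``y ~ 1 + group + covariates`` against the covariates-only model, with the
    exact F reference distribution.  Adjusted group means are evaluated at the
    covariate sample means.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    n = len(y)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group must be coded 0/1")
    Xr = _design(cov, n)
    names = ["intercept"] + (list(cov.columns) if isinstance(cov, pd.DataFrame) else
                             [f"cov{j}" for j in range(Xr.shape[1] - 1)])
    Xf = np.column_stack([Xr, g])
    if n <= Xf.shape[1]:
        raise ValueError("too few observations for the requested model")
    _check_rank(Xf, names + ["group"])
    rss_r = float(_residuals(y, Xr) @ _residuals(y, Xr))
    res_f = _residuals(y, Xf)
    rss_f = float(res_f @ res_f)
    df_den = n - Xf.shape[1]
    f = max(rss_r - rss_f, 0.0) / (rss_f / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    x0 = np.append(Xr.mean(axis=0), 0.0)
    x1 = np.append(Xr.mean(axis=0), 1.0)
    adjusted = {"group0": float(x0 @ beta), "group1": float(x1 @ beta)}
    return GlmResult(f_stat=float(f), df_num=1, df_den=df_den, p_value=p,
                     adjusted_means=adjusted)


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n: int
    n_covariates: int
    p_adjusted: Optional[float] = None


def _partial_r(x: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    rx = _residuals(x, X)
    ry = _residuals(y, X)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # relative floor: a column that is numerically a linear function of the
    # covariates has no residual signal left to correlate
    if sx <= 1e-20 * float(x @ x) or sy <= 1e-20 * float(y @ y):
        raise ValueError("zero residual variance")
    return float(rx @ ry / np.sqrt(sx * sy))


def partial_correlation(
    x,
    y,
    cov: Optional[pd.DataFrame] = None,
    B: int = 1000,
    seed=None,
    ci_level: float = 0.95,
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    r is the Pearson correlation of the OLS residuals of x and y on
    [1, covariates]; the two-tailed p-value uses the t transform with
    df = n - k - 2 (k covariates); the CI is a subject-resampling percentile
    bootstrap (B resamples) in which the residualization is refit per
    resample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = _design(cov, n)
    k = X.shape[1] - 1
    if n <= k + 2:
        raise ValueError("too few observations for partial correlation")
    r = _partial_r(x, y, X)
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    filled = 0
    attempts = 0
    while filled < B:
        if attempts >= _MAX_REDRAW_FACTOR * B:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            boots[filled] = _partial_r(x[idx], y[idx], X[idx])
        except ValueError:
            continue
        filled += 1
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return PartialCorrelationResult(
        r=r, p_value=p, ci_lower=float(lo), ci_upper=float(hi),
        n=n, n_covariates=k,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_lower: float
    ci_upper: float


def _slope(y: np.ndarray, X: np.ndarray, col: int) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[col])


def mediate(
    x,
    m,
    y,
    cov: Optional[pd.DataFrame] = None,
    B: int = 1000,
    seed=None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Simple mediation x -> m -> y with percentile-bootstrap indirect CI.

    a is the slope of x in ``m ~ x + cov``; b and c' come from
    ``y ~ x + m + cov``; c from ``y ~ x + cov``.  The indirect effect a*b is
    bootstrapped by resampling subjects.  For linear models the decomposition
    c = c' + a*b holds exactly.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    C = _design(cov, n)  # [1, cov]

    def paths(xi, mi, yi, Ci):
        Xa = np.column_stack([Ci, xi])
        a = _slope(mi, Xa, Ci.shape[1])
        Xb = np.column_stack([Ci, xi, mi])
        beta_b, *_ = np.linalg.lstsq(Xb, yi, rcond=None)
        c_prime, b = float(beta_b[Ci.shape[1]]), float(beta_b[Ci.shape[1] + 1])
        c = _slope(yi, Xa, Ci.shape[1])
        return a, b, c, c_prime

    a, b, c, c_prime = paths(x, m, y, C)
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        ab, bb, _, _ = paths(x[idx], m[idx], y[idx], C[idx])
        boots[i] = ab * bb
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
                           ci_lower=float(lo), ci_upper=float(hi))


def correlation_family(
    df: pd.DataFrame,
    x_cols: Sequence[str],
    y_cols: Sequence[str],
    cov_cols: Sequence[str],
    B: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """All x-by-y partial correlations corrected as one BH family.

    Returns a tidy frame (x, y, r, p, ci_lower, ci_upper, p_adj, n); the
    FDR family is the full x_cols x y_cols grid, mirroring how the FA
    summaries and the six sleep measures are presented together.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(x_cols) * len(y_cols))
    rows = []
    i = 0
    for xc in x_cols:
        for yc in y_cols:
            sub = df[[xc, yc, *cov_cols]].dropna()
            res = partial_correlation(
                sub[xc], sub[yc], sub[list(cov_cols)], B=B, seed=int(seeds[i])
            )
            rows.append({
                "x": xc, "y": yc, "r": res.r, "p": res.p_value,
                "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                "n": res.n,
            })
            i += 1
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out
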