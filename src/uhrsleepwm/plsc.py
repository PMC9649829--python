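"""Two-block partial least squares correlation (PLS-C).

PLS-C relates a brain block X (n subjects x p = 48 ROI FA values) to a
behaviour block Y (n x q = 6 sleep-wake measures) through the singular value
decomposition of their cross-block correlation matrix

    R = Xr' Yr / (n - 1) = V diag(sigma) U',

where Xr, Yr are the blocks after covariate residualization and column
standardization.  Each latent variable (LV) k pairs an X-salience V[:, k]
with a Y-salience U[:, k]; sigma_k is the cross-block covariance it captures,
and sigma_k^2 / sum_j sigma_j^2 is its "% of covariance explained".

Inference follows the behavioural-PLS conventions:

* omnibus permutation test on the Inertia index (the sum of all singular
  values), permuting rows of Y;
* per-LV permutation p-values from the non-rotated sampling distribution of
  the k-th singular value;
* bootstrap (subjects resampled jointly) percentile CIs for every salience
  element, with each bootstrap solution aligned to the point estimate by an
  orthogonal Procrustes rotation solved on the Y-saliences and applied to
  both blocks.  A salience element is "reliable" when its CI excludes zero.

The user-facing entry point is the :class:`PLSC` model class whose
:meth:`PLSC.fit` returns a :class:`PLSCResults` object; the module-level
functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "residualize",
    "fit_plsc",
    "permutation_test",
    "bootstrap_saliences",
    "covariance_explained",
    "groupwise_plsc",
    "PLSC",
    "PLSCResults",
    "PlscFit",
    "BootstrapCIs",
    "GroupwisePlscResult",
]

_MAX_REDRAW_FACTOR = 10


def _as_matrix(block, what: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), [str(c) for c in block.columns]
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{what}{j}" for j in range(arr.shape[1])]


def residualize(block, cov=None, names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Residualize each column on [1, covariates] and standardize.

    Every column is replaced by its OLS residual on an intercept plus the
    covariates, then scaled to unit sample variance (divisor n - 1).  A column
    whose residual is (numerically) constant raises, naming the column.
    """
    M, auto_names = _as_matrix(block, "col")
    names = list(names) if names is not None else auto_names
    n = M.shape[0]
    if cov is None:
        X = np.ones((n, 1))
    else:
        C, _ = _as_matrix(cov, "cov")
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match block rows")
        X = np.column_stack([np.ones(n), C])
    if n <= X.shape[1]:
        raise ValueError("too few rows to residualize on the covariates")
    if np.isnan(M).any() or np.isnan(X).any():
        raise ValueError("missing entries; apply listwise exclusion first")
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    resid = M - X @ beta
    sd = resid.std(axis=0, ddof=1)
    scale_floor = 1e-12 * max(1.0, float(np.abs(M).max()))
    bad = np.where(sd <= scale_floor)[0]
    if bad.size:
        raise ValueError(
            f"zero residual variance after covariate adjustment in column(s): "
            f"{[names[j] for j in bad]}"
        )
    return resid / sd


@dataclass(frozen=True)
class PlscFit:
    """Point estimates of one PLS-C decomposition."""

    singular_values: np.ndarray  # (K,)
    x_saliences: np.ndarray      # (p, K)
    y_saliences: np.ndarray      # (q, K)
    x_scores: np.ndarray         # (n, K)
    y_scores: np.ndarray         # (n, K)
    cross_block: np.ndarray      # (p, q)

    @property
    def inertia(self) -> float:
        return float(self.singular_values.sum())


def _fix_signs(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude Y-salience element positive per LV.

    Returns the +-1 flips applied (length K); modifies U, V in place.
    """
    K = U.shape[1]
    flips = np.ones(K)
    for k in range(K):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
            flips[k] = -1
    return flips


def fit_plsc(Xr: np.ndarray, Yr: np.ndarray) -> PlscFit:
    """SVD of the cross-block matrix of two residualized/standardized blocks."""
    Xr = np.asarray(Xr, dtype=float)
    Yr = np.asarray(Yr, dtype=float)
    if Xr.shape[0] != Yr.shape[0]:
        raise ValueError("blocks have different numbers of rows")
    if not (np.isfinite(Xr).all() and np.isfinite(Yr).all()):
        raise ValueError("non-finite entries in blocks")
    n = Xr.shape[0]
    R = Xr.T @ Yr / (n - 1)
    P, s, Qt = np.linalg.svd(R, full_matrices=False)
    V, U = P, Qt.T
    _fix_signs(U, V)
    return PlscFit(
        singular_values=s,
        x_saliences=V,
        y_saliences=U,
        x_scores=Xr @ V,
        y_scores=Yr @ U,
        cross_block=R,
    )


def covariance_explained(sigma) -> np.ndarray:
    """sigma_k^2 / sum_j sigma_j^2 — the per-LV cross-block covariance share."""
    s = np.asarray(sigma, dtype=float)
    if (s < 0).any():
        raise ValueError("singular values must be non-negative")
    total = float((s ** 2).sum())
    if total == 0:
        raise ValueError("all singular values are zero")
    return s ** 2 / total


def _batched_cross_svd(Xb: np.ndarray, Yb: np.ndarray, n: int):
    """Cross-block SVDs for a stack of paired blocks (chunk, n, p/q)."""
    R = np.einsum("cnp,cnq->cpq", Xb, Yb) / (n - 1)
    return np.linalg.svd(R, full_matrices=False)


def permutation_test(
    Xr: np.ndarray, Yr: np.ndarray, n_perm: int = 10000, seed=None
) -> tuple[float, np.ndarray]:
    """Omnibus (Inertia) and per-LV permutation p-values.

    Rows of Yr are shuffled relative to Xr; per permutation the PLS-C is
    refit without rotation and (a) the Inertia (sum of singular values) and
    (b) each k-th singular value are compared against the observed ones.
    p-values use the +1 correction, so the smallest attainable value is
    1 / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for a stable p-value")
    Xr = np.asarray(Xr, dtype=float)
    Yr = np.asarray(Yr, dtype=float)
    n = Xr.shape[0]
    obs = fit_plsc(Xr, Yr)
    s_obs = obs.singular_values
    inertia_obs = obs.inertia
    rng = np.random.default_rng(seed)

    count_omni = 0
    count_lv = np.zeros_like(s_obs)
    chunk = max(1, min(n_perm, int(8e6 / max(1, n * Yr.shape[1]))))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((c, n)), axis=1)  # c independent permutations
        Yp = Yr[idx]
        s_perm = np.linalg.svd(
            np.einsum("np,cnq->cpq", Xr, Yp) / (n - 1), compute_uv=False
        )
        count_omni += int((s_perm.sum(axis=1) >= inertia_obs).sum())
        count_lv += (s_perm >= s_obs[None, :]).sum(axis=0)
        done += c
    p_omni = (1.0 + count_omni) / (1.0 + n_perm)
    p_lv = (1.0 + count_lv) / (1.0 + n_perm)
    return float(p_omni), p_lv


@dataclass(frozen=True)
class BootstrapCIs:
    """Percentile bootstrap CIs for every salience element."""

    x_lower: np.ndarray  # (p, K)
    x_upper: np.ndarray
    y_lower: np.ndarray  # (q, K)
    y_upper: np.ndarray
    n_boot: int
    ci_level: float

    @property
    def x_reliable(self) -> np.ndarray:
        """CI excludes zero."""
        return (self.x_lower > 0) | (self.x_upper < 0)

    @property
    def y_reliable(self) -> np.ndarray:
        return (self.y_lower > 0) | (self.y_upper < 0)


def _standardize_stack(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns of each block in a (c, n, m) stack; flag collapses."""
    centered = B - B.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    collapsed = (sd <= 1e-12).any(axis=(1, 2))
    sd = np.where(sd <= 1e-12, 1.0, sd)
    return centered / sd, collapsed


def bootstrap_saliences(
    Xr: np.ndarray,
    Yr: np.ndarray,
    n_boot: int = 10000,
    seed=None,
    ci_level: float = 0.95,
) -> BootstrapCIs:
    """Procrustes-aligned percentile bootstrap CIs for the saliences.

    Subjects are resampled jointly with replacement; each resampled pair of
    blocks is re-centered/re-standardized and refit; the bootstrap saliences
    are rotated onto the point estimate by the orthogonal Procrustes solution
    computed on the Y-saliences and applied to both blocks.  Resamples in
    which a block column collapses to a constant are redrawn (capped).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    Xr = np.asarray(Xr, dtype=float)
    Yr = np.asarray(Yr, dtype=float)
    n, p = Xr.shape
    q = Yr.shape[1]
    ref = fit_plsc(Xr, Yr)
    U0 = ref.y_saliences
    K = U0.shape[1]
    rng = np.random.default_rng(seed)

    u_samples = np.empty((n_boot, q, K))
    v_samples = np.empty((n_boot, p, K))
    filled = 0
    attempts = 0
    chunk = max(1, min(n_boot, int(8e6 / max(1, n * p))))
    while filled < n_boot:
        if attempts >= _MAX_REDRAW_FACTOR * n_boot:
            raise RuntimeError("too many rank-collapsed bootstrap resamples")
        c = min(chunk, n_boot - filled)
        attempts += c
        idx = rng.integers(0, n, size=(c, n))
        Xb, bad_x = _standardize_stack(Xr[idx])
        Yb, bad_y = _standardize_stack(Yr[idx])
        ok = ~(bad_x | bad_y)
        if not ok.any():
            continue
        P, _, Qt = _batched_cross_svd(Xb[ok], Yb[ok], n)
        Ub = Qt.transpose(0, 2, 1)  # (c_ok, q, K)
        Vb = P                      # (c_ok, p, K)
        # orthogonal Procrustes on Y-saliences: Q = argmin ||Ub Q - U0||
        M = np.einsum("cqk,ql->ckl", Ub, U0)
        A, _, Bt = np.linalg.svd(M)
        Q = A @ Bt
        Ub = Ub @ Q
        Vb = Vb @ Q
        take = min(Ub.shape[0], n_boot - filled)
        u_samples[filled:filled + take] = Ub[:take]
        v_samples[filled:filled + take] = Vb[:take]
        filled += take
    alpha = 1.0 - ci_level
    qs = [alpha / 2, 1 - alpha / 2]
    u_lo, u_hi = np.quantile(u_samples, qs, axis=0)
    v_lo, v_hi = np.quantile(v_samples, qs, axis=0)
    return BootstrapCIs(
        x_lower=v_lo, x_upper=v_hi, y_lower=u_lo, y_upper=u_hi,
        n_boot=n_boot, ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class PLSC:
    """Two-block PLS correlation model with covariate residualization.

    Parameters
    ----------
    X, Y : array-like or DataFrame, shape (n, p) and (n, q)
        Brain and behaviour blocks (rows are subjects).
    covariates : array-like or DataFrame, optional
        Nuisance variables removed from every column of both blocks by OLS
        before the decomposition.
    x_names, y_names : sequences of str, optional
        Column names used in results tables; inferred from DataFrames.

    Examples
    --------
    >>> model = PLSC.from_dataframe(df, x_cols=roi_cols, y_cols=sleep_cols,
    ...                             cov_cols=["age", "sex"])
    >>> res = model.fit(n_perm=1000, n_boot=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, X, Y, covariates=None, x_names=None, y_names=None):
        self.X, auto_x = _as_matrix(X, "x")
        self.Y, auto_y = _as_matrix(Y, "y")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y have different numbers of rows")
        self.covariates = covariates
        self.x_names = list(x_names) if x_names is not None else auto_x
        self.y_names = list(y_names) if y_names is not None else auto_y
        n_cov = 0 if covariates is None else _as_matrix(covariates, "cov")[0].shape[1]
        if self.X.shape[0] <= n_cov + 2:
            raise ValueError("too few subjects for the covariate set")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_cols, y_cols, cov_cols=None):
        cols = list(x_cols) + list(y_cols) + (list(cov_cols) if cov_cols else [])
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in frame: {missing}")
        sub = df[cols].dropna()
        cov = sub[list(cov_cols)] if cov_cols else None
        return cls(sub[list(x_cols)], sub[list(y_cols)], covariates=cov,
                   x_names=list(x_cols), y_names=list(y_cols))

    def residualized(self) -> tuple[np.ndarray, np.ndarray]:
        Xr = residualize(self.X, self.covariates, names=self.x_names)
        Yr = residualize(self.Y, self.covariates, names=self.y_names)
        return Xr, Yr

    def fit(
        self,
        n_perm: int = 10000,
        n_boot: int = 10000,
        seed=None,
        ci_level: float = 0.95,
        covariance_threshold: float = 0.05,
    ) -> "PLSCResults":
        Xr, Yr = self.residualized()
        point = fit_plsc(Xr, Yr)
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        perm_seed, boot_seed = ss.spawn(2)
        p_omni, p_lv = permutation_test(Xr, Yr, n_perm=n_perm, seed=perm_seed)
        cis = bootstrap_saliences(Xr, Yr, n_boot=n_boot, seed=boot_seed,
                                  ci_level=ci_level)
        return PLSCResults(
            model=self, point=point, p_omnibus=p_omni, p_lv=p_lv,
            bootstrap=cis, covariance_threshold=covariance_threshold,
        )


@dataclass
class PLSCResults:
    """Fitted PLS-C decomposition with permutation and bootstrap inference."""

    model: PLSC
    point: PlscFit
    p_omnibus: float
    p_lv: np.ndarray
    bootstrap: Optional[BootstrapCIs]
    covariance_threshold: float = 0.05

    # -- convenience accessors -------------------------------------------
    @property
    def singular_values(self) -> np.ndarray:
        return self.point.singular_values

    @property
    def inertia(self) -> float:
        return self.point.inertia

    @property
    def covariance_explained(self) -> np.ndarray:
        return covariance_explained(self.point.singular_values)

    @property
    def x_saliences(self) -> np.ndarray:
        return self.point.x_saliences

    @property
    def y_saliences(self) -> np.ndarray:
        return self.point.y_saliences

    @property
    def x_scores(self) -> np.ndarray:
        return self.point.x_scores

    @property
    def y_scores(self) -> np.ndarray:
        return self.point.y_scores

    @property
    def reportable(self) -> np.ndarray:
        """LVs worth reporting: > threshold share of covariance and p < 0.05."""
        return (self.covariance_explained > self.covariance_threshold) & (
            self.p_lv < 0.05
        )

    def salience_table(self) -> pd.DataFrame:
        """Long-format table of saliences, CIs and reliability flags."""
        rows = []
        K = len(self.singular_values)
        for block, names, sal, lo, hi, rel in (
            ("X", self.model.x_names, self.x_saliences,
             self.bootstrap.x_lower if self.bootstrap else None,
             self.bootstrap.x_upper if self.bootstrap else None,
             self.bootstrap.x_reliable if self.bootstrap else None),
            ("Y", self.model.y_names, self.y_saliences,
             self.bootstrap.y_lower if self.bootstrap else None,
             self.bootstrap.y_upper if self.bootstrap else None,
             self.bootstrap.y_reliable if self.bootstrap else None),
        ):
            for j, name in enumerate(names):
                for k in range(K):
                    rows.append({
                        "block": block, "variable": name, "lv": k + 1,
                        "salience": sal[j, k],
                        "ci_lower": lo[j, k] if lo is not None else np.nan,
                        "ci_upper": hi[j, k] if hi is not None else np.nan,
                        "reliable": bool(rel[j, k]) if rel is not None else False,
                    })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the full result."""
        d = {
            "singular_values": self.singular_values.tolist(),
            "inertia": self.inertia,
            "p_omnibus": self.p_omnibus,
            "p_lv": np.asarray(self.p_lv).tolist(),
            "covariance_explained": self.covariance_explained.tolist(),
            "reportable": self.reportable.tolist(),
            "x_names": self.model.x_names,
            "y_names": self.model.y_names,
            "x_saliences": self.x_saliences.tolist(),
            "y_saliences": self.y_saliences.tolist(),
        }
        if self.bootstrap is not None:
            d.update({
                "x_ci_lower": self.bootstrap.x_lower.tolist(),
                "x_ci_upper": self.bootstrap.x_upper.tolist(),
                "y_ci_lower": self.bootstrap.y_lower.tolist(),
                "y_ci_upper": self.bootstrap.y_upper.tolist(),
                "x_reliable": self.bootstrap.x_reliable.tolist(),
                "y_reliable": self.bootstrap.y_reliable.tolist(),
                "n_boot": self.bootstrap.n_boot,
                "ci_level": self.bootstrap.ci_level,
            })
        return d

    def summary(self) -> str:
        """Plain-text summary table of the latent variables."""
        frac = self.covariance_explained
        lines = [
            "PLS correlation results",
            "=" * 64,
            f"n subjects: {self.model.X.shape[0]}   "
            f"p (X): {self.model.X.shape[1]}   q (Y): {self.model.Y.shape[1]}",
            f"Inertia (sum of singular values): {self.inertia:.4f}   "
            f"omnibus permutation p = {self.p_omnibus:.4g}",
            "-" * 64,
            f"{'LV':>3} {'sigma':>9} {'% covar':>9} {'perm p':>9} {'report':>7}",
        ]
        for k, s in enumerate(self.singular_values):
            lines.append(
                f"{k + 1:>3} {s:>9.4f} {100 * frac[k]:>8.2f}% "
                f"{self.p_lv[k]:>9.4g} {'yes' if self.reportable[k] else 'no':>7}"
            )
        if self.bootstrap is not None:
            n_rel = int(self.bootstrap.x_reliable[:, 0].sum())
            lines.append("-" * 64)
            lines.append(
                f"bootstrap: {self.bootstrap.n_boot} resamples, "
                f"{100 * self.bootstrap.ci_level:.0f}% CIs; "
                f"{n_rel}/{len(self.model.x_names)} X-saliences reliable on LV1"
            )
        return "\n".join(lines)

    def plot_saliences(self, lv: int = 1, ax=None):
        """Bar plot of LV saliences with bootstrap CIs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        k = lv - 1
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        names = self.model.x_names + self.model.y_names
        vals = np.concatenate([self.x_saliences[:, k], self.y_saliences[:, k]])
        pos = np.arange(len(names))
        ax.bar(pos, vals, color="steelblue")
        if self.bootstrap is not None:
            lo = np.concatenate([self.bootstrap.x_lower[:, k],
                                 self.bootstrap.y_lower[:, k]])
            hi = np.concatenate([self.bootstrap.x_upper[:, k],
                                 self.bootstrap.y_upper[:, k]])
            ax.errorbar(pos, vals, yerr=[vals - lo, hi - vals], fmt="none",
                        ecolor="black", lw=0.8)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xticks(pos)
        ax.set_xticklabels(names, rotation=90, fontsize=6)
        ax.set_ylabel(f"LV{lv} salience")
        return ax


# ---------------------------------------------------------------------------
# Group-wise analysis
# ---------------------------------------------------------------------------

@dataclass
class GroupwisePlscResult:
    within: dict            # group label -> PLSCResults
    contrast_p: float       # group-difference omnibus permutation p
    contrast_inertia: float


def _contrast_statistic(Xr, Yr, labels, groups) -> float:
    """Inertia of the mean-centered stack of group-wise cross-block matrices."""
    n = Xr.shape[0]
    Rs = []
    for g in groups:
        m = labels == g
        Rs.append(Xr[m].T @ Yr[m] / (m.sum() - 1))
    Rbar = np.mean(Rs, axis=0)
    stacked = np.vstack([R - Rbar for R in Rs])
    return float(np.linalg.svd(stacked, compute_uv=False).sum())


def groupwise_plsc(
    X,
    Y,
    groups,
    cov=None,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed=None,
    x_names=None,
    y_names=None,
) -> GroupwisePlscResult:
    """Within-group PLS-C analyses plus a group-contrast omnibus test.

    Within-group: each group is residualized on the covariates within the
    group and analysed independently (permutation + bootstrap inference).

    Contrast: both blocks are residualized across the pooled sample; each
    group's cross-block matrix is computed, the group-average matrix is
    subtracted, the matrices are stacked, and the inertia of the stack is the
    test statistic.  Its null distribution comes from permuting group
    membership (group sizes preserved).
    """
    X, auto_x = _as_matrix(X, "x")
    Y, auto_y = _as_matrix(Y, "y")
    labels = np.asarray(groups)
    unique = list(pd.unique(labels))
    cov_arr = None if cov is None else _as_matrix(cov, "cov")[0]
    n_cov = 0 if cov_arr is None else cov_arr.shape[1]
    for g in unique:
        if (labels == g).sum() < n_cov + 3:
            raise ValueError(f"group {g!r} too small for the covariate set")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(unique) + 1)

    within = {}
    for g, s in zip(unique, child[:-1]):
        m = labels == g
        model = PLSC(
            X[m], Y[m],
            covariates=None if cov_arr is None else cov_arr[m],
            x_names=x_names or auto_x, y_names=y_names or auto_y,
        )
        within[g] = model.fit(n_perm=n_perm, n_boot=n_boot, seed=s)

    # contrast on pooled residualization
    Xr = residualize(X, cov_arr, names=x_names or auto_x)
    Yr = residualize(Y, cov_arr, names=y_names or auto_y)
    obs = _contrast_statistic(Xr, Yr, labels, unique)
    rng = np.random.default_rng(child[-1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _contrast_statistic(Xr, Yr, perm, unique) >= obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return GroupwisePlscResult(within=within, contrast_p=p, contrast_inertia=obs)
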