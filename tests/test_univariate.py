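"""Covariate-adjusted group tests, partial correlations, FDR, mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uhrsleepwm import (
    bh_fdr,
    correlation_family,
    glm_group_test,
    mediate,
    partial_correlation,
)


def residual_corr_oracle(x, y, C):
    """Two-stage OLS-then-Pearson via explicit normal equations."""
    X = np.column_stack([np.ones(len(x)), C]) if C is not None else \
        np.ones((len(x), 1))
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    rx, ry = x - H @ x, y - H @ y
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestGlmGroupTest:
    def test_equals_squared_t_without_covariates(self, rng):
        y = rng.standard_normal(40)
        g = np.repeat([0, 1], 20)
        res = glm_group_test(y, g)
        t = stats.ttest_ind(y[g == 1], y[g == 0]).statistic
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """12-subject design vs F computed by explicit matrix algebra."""
        n = 12
        g = np.array([0, 1] * 6, dtype=float)
        cov = pd.DataFrame({"age": rng.uniform(18, 30, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        y = rng.standard_normal(n)
        Xf = np.column_stack([np.ones(n), cov.to_numpy(), g])
        Xr = Xf[:, :-1]

        def rss(X):
            beta = np.linalg.inv(X.T @ X) @ X.T @ y
            r = y - X @ beta
            return float(r @ r)

        df_den = n - Xf.shape[1]
        f_oracle = (rss(Xr) - rss(Xf)) / (rss(Xf) / df_den)
        res = glm_group_test(y, g, cov)
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-10)
        assert res.p_value == pytest.approx(stats.f.sf(f_oracle, 1, df_den))
        assert res.df_den == df_den

    def test_null_type_i_error_controlled(self, rng):
        """Rejection rate near alpha when y is independent of group."""
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = rng.standard_normal(30)
            g = rng.permutation(np.repeat([0, 1], 15)).astype(float)
            cov = pd.DataFrame({"c": rng.standard_normal(30)})
            if glm_group_test(y, g, cov).p_value < 0.05:
                rejections += 1
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= rejections <= hi

    def test_collinear_design_rejected(self, rng):
        y = rng.standard_normal(20)
        g = np.repeat([0, 1], 10).astype(float)
        cov = pd.DataFrame({"a": np.arange(20.0), "b": 2 * np.arange(20.0)})
        with pytest.raises(ValueError, match="collinear"):
            glm_group_test(y, g, cov)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 30))
        res = partial_correlation(x, y, B=200, seed=0)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(25)
        cov = pd.DataFrame({"c": rng.standard_normal(25)})
        res = partial_correlation(x, x.copy(), cov, B=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_eight_subject_oracle(self, rng):
        x, y = rng.standard_normal((2, 8))
        C = rng.standard_normal((8, 2))
        res = partial_correlation(x, y, pd.DataFrame(C), B=200, seed=0)
        assert res.r == pytest.approx(residual_corr_oracle(x, y, C), abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(1, 4))
            x, y = rng.standard_normal((2, n))
            C = rng.standard_normal((n, k))
            res = partial_correlation(x, y, pd.DataFrame(C), B=200, seed=1)
            assert res.r == pytest.approx(residual_corr_oracle(x, y, C),
                                          abs=1e-12)

    def test_cross_checked_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 50
        df = pd.DataFrame(rng.standard_normal((n, 4)),
                          columns=["x", "y", "c1", "c2"])
        res = partial_correlation(df["x"], df["y"], df[["c1", "c2"]],
                                  B=200, seed=0)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            rel=1e-6)

    def test_bootstrap_ci_reproducible_and_ordered(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        a = partial_correlation(x, y, B=500, seed=9)
        b = partial_correlation(x, y, B=500, seed=9)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
        assert a.ci_lower < a.ci_upper

    def test_zero_residual_variance_rejected(self, rng):
        c = rng.standard_normal(20)
        cov = pd.DataFrame({"c": c})
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(2 * c + 1, rng.standard_normal(20), cov,
                                B=200, seed=0)


def bh_oracle(p):
    """Brute-force step-up: q_i = min_{j>=i} p_(j) * m / j, in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank - 1, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_evenly_spaced_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_equal_ps_fixed_point(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 25)))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestMediation:
    def test_ols_decomposition_identity(self, rng):
        """c = c' + a*b exactly on any fixed dataset."""
        n = 60
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.3 * x + 0.4 * m + rng.standard_normal(n)
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        res = mediate(x, m, y, cov, B=200, seed=0)
        assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_no_mediation_ci_covers_zero(self, rng):
        n = 200
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)  # independent of y given x
        y = 0.5 * x + rng.standard_normal(n)
        res = mediate(x, m, y, B=500, seed=3)
        assert res.ci_lower < 0 < res.ci_upper
        assert abs(res.indirect) < 0.15

    def test_planted_indirect_effect_recovered(self, rng):
        n = 500
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n) * 0.5
        y = 0.4 * m + 0.1 * x + rng.standard_normal(n) * 0.5
        res = mediate(x, m, y, B=500, seed=4)
        assert res.indirect == pytest.approx(0.2, abs=0.05)
        assert res.ci_lower > 0


class TestCorrelationFamily:
    def test_family_layout_and_fdr(self, rng):
        n = 40
        df = pd.DataFrame({
            "fa1": rng.standard_normal(n), "fa2": rng.standard_normal(n),
            "s1": rng.standard_normal(n), "s2": rng.standard_normal(n),
            "age": rng.uniform(18, 30, n),
        })
        out = correlation_family(df, ("fa1", "fa2"), ("s1", "s2"), ("age",),
                                 B=200, seed=0)
        assert len(out) == 4
        np.testing.assert_allclose(out["p_adj"], bh_oracle(out["p"].to_numpy()),
                                   atol=1e-12)
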