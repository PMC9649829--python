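"""PLS correlation: decomposition, permutation, bootstrap, group contrast."""

import numpy as np
import pandas as pd
import pytest

from uhrsleepwm import PLSC
from uhrsleepwm.plsc import (
    bootstrap_saliences,
    covariance_explained,
    fit_plsc,
    groupwise_plsc,
    permutation_test,
    residualize,
)


def standardize(M):
    M = M - M.mean(0)
    return M / M.std(0, ddof=1)


def planted_blocks(n, p, q, rng, strength=1.0, noise=1.0):
    """Rank-one latent structure shared by both blocks."""
    z = rng.standard_normal(n)
    u = rng.standard_normal(p)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(q)
    v /= np.linalg.norm(v)
    X = strength * np.outer(z, u) + noise * rng.standard_normal((n, p))
    Y = strength * np.outer(z, v) + noise * rng.standard_normal((n, q))
    return standardize(X), standardize(Y), u, v


class TestResidualize:
    def test_matches_two_stage_ols_oracle(self, rng):
        n, m, k = 20, 5, 2
        M = rng.standard_normal((n, m))
        C = rng.standard_normal((n, k))
        out = residualize(M, C)
        X = np.column_stack([np.ones(n), C])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for j in range(m):
            r = M[:, j] - H @ M[:, j]
            r /= r.std(ddof=1)
            np.testing.assert_allclose(out[:, j], r, atol=1e-12)

    def test_orthogonal_centered_column_only_rescaled(self, rng):
        n = 40
        c = rng.standard_normal(n)
        c -= c.mean()
        x = rng.standard_normal(n)
        x -= x.mean()
        x -= (x @ c / (c @ c)) * c  # orthogonal to centered covariate and to 1
        out = residualize(x[:, None], c[:, None])
        np.testing.assert_allclose(out[:, 0], x / x.std(ddof=1), atol=1e-10)

    def test_exact_linear_function_of_covariates_errors(self, rng):
        c = rng.standard_normal(30)
        M = np.column_stack([2.0 * c + 1.0, rng.standard_normal(30)])
        with pytest.raises(ValueError, match="zero residual variance"):
            residualize(M, c[:, None], names=["lin", "ok"])


class TestFit:
    def test_self_correlation_single_column(self, rng):
        x = standardize(rng.standard_normal((30, 1)))
        fit = fit_plsc(x, x)
        assert fit.singular_values[0] == pytest.approx(1.0)
        assert fit.x_saliences[0, 0] == pytest.approx(1.0)
        assert fit.y_saliences[0, 0] == pytest.approx(1.0)

    def test_exactly_orthogonal_blocks_give_zero(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        Y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        fit = fit_plsc(X, Y)
        np.testing.assert_allclose(fit.singular_values, 0.0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        """sigma/U/V from SVD match brute-force eigen-analysis of R'R, RR'."""
        for _ in range(20):
            X = standardize(rng.standard_normal((30, 4)))
            Y = standardize(rng.standard_normal((30, 3)))
            fit = fit_plsc(X, Y)
            R = X.T @ Y / 29
            w_u, U = np.linalg.eigh(R.T @ R)
            w_v, V = np.linalg.eigh(R @ R.T)
            sig = np.sqrt(np.maximum(w_u[::-1], 0.0))
            np.testing.assert_allclose(fit.singular_values, sig, atol=1e-10)
            for k in range(3):
                u_o = U[:, ::-1][:, k]
                v_o = V[:, ::-1][:, k]
                assert abs(abs(u_o @ fit.y_saliences[:, k]) - 1) < 1e-8
                assert abs(abs(v_o @ fit.x_saliences[:, k]) - 1) < 1e-8

    def test_conservation_and_score_covariance(self, rng):
        X = standardize(rng.standard_normal((40, 6)))
        Y = standardize(rng.standard_normal((40, 4)))
        fit = fit_plsc(X, Y)
        assert np.sum(fit.singular_values ** 2) == pytest.approx(
            np.linalg.norm(fit.cross_block, "fro") ** 2, abs=1e-10)
        # cov(Lx_k, Ly_k) = sigma_k
        for k, s in enumerate(fit.singular_values):
            c = fit.x_scores[:, k] @ fit.y_scores[:, k] / 39
            assert c == pytest.approx(s, abs=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = standardize(rng.standard_normal((25, 5)))
        Y = standardize(rng.standard_normal((25, 3)))
        fit = fit_plsc(X, Y)
        for k in range(3):
            j = np.argmax(np.abs(fit.y_saliences[:, k]))
            assert fit.y_saliences[j, k] > 0


class TestCovarianceExplained:
    def test_arithmetic(self):
        np.testing.assert_allclose(covariance_explained([4.0, 3.0]),
                                   [0.64, 0.36], atol=1e-12)

    def test_single_nonzero(self):
        np.testing.assert_allclose(covariance_explained([2.0, 0.0, 0.0]),
                                   [1.0, 0.0, 0.0])

    def test_sums_to_one(self, rng):
        s = rng.uniform(0, 5, size=6)
        assert covariance_explained(s).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            covariance_explained([0.0, 0.0])


class TestPermutation:
    def test_floor_p_value_with_strong_structure(self, rng):
        X, Y, *_ = planted_blocks(100, 6, 4, rng, strength=3.0, noise=0.3)
        p_omni, p_lv = permutation_test(X, Y, n_perm=500, seed=0)
        assert p_omni == pytest.approx(1 / 501)
        assert p_lv[0] == pytest.approx(1 / 501)

    def test_small_n_perm_rejected(self, rng):
        X = standardize(rng.standard_normal((20, 3)))
        with pytest.raises(ValueError, match="at least 100"):
            permutation_test(X, X, n_perm=50, seed=0)

    def test_seeded_determinism(self, rng):
        X = standardize(rng.standard_normal((30, 5)))
        Y = standardize(rng.standard_normal((30, 3)))
        a = permutation_test(X, Y, n_perm=300, seed=11)
        b = permutation_test(X, Y, n_perm=300, seed=11)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_null_p_roughly_uniform(self, rng):
        """Omnibus p under independent blocks is not concentrated low."""
        ps = []
        for _ in range(60):
            X = standardize(rng.standard_normal((30, 5)))
            Y = standardize(rng.standard_normal((30, 3)))
            ps.append(permutation_test(X, Y, n_perm=200, seed=rng.integers(1e6))[0])
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.mean(ps) == pytest.approx(0.5, abs=0.15)


class TestBootstrap:
    def test_seeded_determinism(self, rng):
        X, Y, *_ = planted_blocks(60, 5, 3, rng)
        a = bootstrap_saliences(X, Y, n_boot=300, seed=4)
        b = bootstrap_saliences(X, Y, n_boot=300, seed=4)
        np.testing.assert_array_equal(a.x_lower, b.x_lower)
        np.testing.assert_array_equal(a.y_upper, b.y_upper)

    def test_sign_equivariance_on_negated_column(self, rng):
        X, Y, *_ = planted_blocks(60, 5, 3, rng, strength=2.0, noise=0.5)
        a = bootstrap_saliences(X, Y, n_boot=300, seed=4)
        X2 = X.copy()
        X2[:, 2] *= -1
        b = bootstrap_saliences(X2, Y, n_boot=300, seed=4)
        np.testing.assert_allclose(b.x_lower[2], -a.x_upper[2], atol=1e-10)
        np.testing.assert_allclose(b.x_upper[2], -a.x_lower[2], atol=1e-10)
        np.testing.assert_allclose(b.x_lower[0], a.x_lower[0], atol=1e-10)

    def test_reliability_flag_matches_ci(self, rng):
        X, Y, *_ = planted_blocks(80, 5, 3, rng, strength=2.0, noise=0.5)
        cis = bootstrap_saliences(X, Y, n_boot=300, seed=1)
        manual = (cis.x_lower > 0) | (cis.x_upper < 0)
        np.testing.assert_array_equal(cis.x_reliable, manual)

    def test_small_n_boot_rejected(self, rng):
        X = standardize(rng.standard_normal((20, 3)))
        with pytest.raises(ValueError, match="at least 200"):
            bootstrap_saliences(X, X, n_boot=50, seed=0)


class TestModelInterface:
    def make_frame(self, rng, n=50):
        df = pd.DataFrame(rng.standard_normal((n, 5)),
                          columns=["x1", "x2", "x3", "y1", "y2"])
        df["age"] = rng.uniform(20, 30, n)
        return df

    def test_from_dataframe_and_summary(self, rng):
        df = self.make_frame(rng)
        model = PLSC.from_dataframe(df, ["x1", "x2", "x3"], ["y1", "y2"],
                                    cov_cols=["age"])
        res = model.fit(n_perm=200, n_boot=200, seed=0)
        text = res.summary()
        assert "Inertia" in text and "omnibus" in text
        table = res.salience_table()
        assert set(table["block"]) == {"X", "Y"}
        assert len(table) == (3 + 2) * 2  # (p + q) * K
        d = res.to_dict()
        assert len(d["singular_values"]) == 2
        assert res.covariance_explained.sum() == pytest.approx(1.0)

    def test_missing_column_reported(self, rng):
        df = self.make_frame(rng)
        with pytest.raises(KeyError, match="nope"):
            PLSC.from_dataframe(df, ["x1", "nope"], ["y1"])

    def test_fit_reproducible_with_seed(self, rng):
        df = self.make_frame(rng)
        model = PLSC.from_dataframe(df, ["x1", "x2", "x3"], ["y1", "y2"],
                                    cov_cols=["age"])
        a = model.fit(n_perm=200, n_boot=200, seed=5)
        b = model.fit(n_perm=200, n_boot=200, seed=5)
        assert a.p_omnibus == b.p_omnibus
        np.testing.assert_array_equal(a.bootstrap.x_lower, b.bootstrap.x_lower)


class TestGroupwise:
    def test_structure_in_one_group_only(self, rng):
        nA = nB = 80
        XA, YA, *_ = planted_blocks(nA, 6, 4, rng, strength=2.0, noise=0.5)
        XB = standardize(rng.standard_normal((nB, 6)))
        YB = standardize(rng.standard_normal((nB, 4)))
        X = np.vstack([XA, XB])
        Y = np.vstack([YA, YB])
        labels = np.array(["A"] * nA + ["B"] * nB)
        res = groupwise_plsc(X, Y, labels, n_perm=300, n_boot=300, seed=2)
        assert res.within["A"].p_omnibus < 0.05
        assert res.within["B"].p_omnibus > 0.05
        assert res.contrast_p < 0.05

    def test_identical_groups_contrast_null(self, rng):
        X = standardize(rng.standard_normal((60, 5)))
        Y = standardize(rng.standard_normal((60, 3)))
        labels = np.repeat(["A", "B"], 30)
        res = groupwise_plsc(X, Y, labels, n_perm=300, n_boot=200, seed=3)
        assert res.contrast_p > 0.01

    def test_too_small_group_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 2))
        labels = np.array(["A"] * 8 + ["B"] * 2)
        cov = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="too small"):
            groupwise_plsc(X, Y, labels, cov=cov, n_perm=100, n_boot=200, seed=0)
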