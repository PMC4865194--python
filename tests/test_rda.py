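"""RDA, partial RDA, adjusted R², variation partitioning, permutation tests."""

import numpy as np
import pytest

import betascape as b
from oracles import hat_matrix_fit


class TestAdjustedR2:
    def test_ezekiel_spot_check(self):
        assert b.adjusted_r2(0.5, 11, 1) == pytest.approx(4.0 / 9.0, abs=1e-12)

    def test_zero_fit_closed_form(self):
        # r2=0 -> -rank/(n-rank-1); n=11, rank 1 gives -1/9
        assert b.adjusted_r2(0.0, 11, 1) == pytest.approx(-1.0 / 9.0, abs=1e-12)


class TestRda:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(0)
        y = rng.random((12, 1))
        fit = b.rda(y, y.copy())
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor_closed_form(self):
        n = 11
        y = np.zeros((n, 1))
        y[:, 0] = np.sin(np.arange(n))
        yc = y - y.mean()
        x = np.ones((n, 1))
        x[:, 0] = np.cos(7 * np.arange(n))
        xc = (x - x.mean())[:, 0]
        xc -= (xc @ yc[:, 0]) / (yc[:, 0] @ yc[:, 0]) * yc[:, 0]  # force orthogonality
        fit = b.rda(y, xc[:, None])
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_adj == pytest.approx(-1.0 / 9.0, abs=1e-10)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(1)
        Y = rng.random((20, 5))
        X = rng.random((20, 3))
        fit = b.rda(Y, X)
        expected = hat_matrix_fit(Y, X)
        assert np.allclose(fit.fitted, expected, atol=1e-10)
        Yc = Y - Y.mean(axis=0)
        assert fit.r2 == pytest.approx((expected ** 2).sum() / (Yc ** 2).sum(), abs=1e-12)
        assert np.allclose(fit.fitted + fit.residuals, Yc, atol=1e-10)

    def test_rank_deficient_x_uses_effective_rank(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 1))
        X = np.hstack([x, 2 * x, x + 3])  # rank 1 after centring
        fit = b.rda(rng.random((15, 2)), X)
        assert fit.rank_x == 1

    def test_r2_invariant_to_orthonormal_rotation(self):
        rng = np.random.default_rng(3)
        Y = rng.random((25, 4))
        X = rng.random((25, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert b.rda(Y, X).r2 == pytest.approx(b.rda(Y, X @ Q).r2, abs=1e-12)

    def test_axis_fractions_non_increasing_and_sum_to_r2(self):
        rng = np.random.default_rng(4)
        fit = b.rda(rng.random((30, 6)), rng.random((30, 2)))
        f = fit.axis_variance_fraction
        assert (np.diff(f) <= 1e-12).all()
        assert f.sum() == pytest.approx(fit.r2, abs=1e-10)

    def test_too_few_sites_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            b.rda(rng.random((4, 2)), rng.random((4, 3)))


class TestPartialRda:
    def test_empty_covariables_equals_plain_rda(self):
        rng = np.random.default_rng(6)
        Y, X = rng.random((20, 3)), rng.random((20, 2))
        a = b.partial_rda(Y, X, None)
        c = b.rda(Y, X)
        assert a.r2 == pytest.approx(c.r2, abs=1e-12)

    def test_x_equal_z_conditional_zero(self):
        rng = np.random.default_rng(7)
        Y, X = rng.random((20, 3)), rng.random((20, 2))
        fit = b.partial_rda(Y, X, X.copy())
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.rank_x == 0

    def test_orthogonal_sets_make_partialling_a_noop(self):
        rng = np.random.default_rng(8)
        n = 40
        M = rng.standard_normal((n, 4))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X, Z = Q[:, :2], Q[:, 2:]
        Y = X @ rng.random((2, 3)) + Z @ rng.random((2, 3)) + 0.1 * rng.random((n, 3))
        assert b.partial_rda(Y, X, Z).r2 == pytest.approx(b.rda(Y, X).r2, abs=1e-10)


class TestVarpart:
    def _orthogonal_sets(self, n=200, seed=9):
        rng = np.random.default_rng(seed)
        M = rng.standard_normal((n, 8))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        return [Q[:, 2 * i:2 * i + 2] for i in range(4)]

    def test_orthogonal_construction_recovers_marginals(self):
        A, B, C, D = self._orthogonal_sets()
        rng = np.random.default_rng(10)
        n = A.shape[0]
        Y = (2 * A @ rng.random((2, 5)) + B @ rng.random((2, 5))
             + 0.5 * C @ rng.random((2, 5)) + rng.standard_normal((n, 5)))
        vp = b.varpart(Y, {"A": A, "B": B, "C": C, "D": D}, test_fractions=False)
        for name, X in zip("ABCD", (A, B, C, D)):
            assert vp.fraction_table[name] == pytest.approx(
                b.rda(Y, X).r2_adj, abs=0.01)
        shared = [v for k, v in vp.fraction_table.items() if "&" in k]
        assert max(abs(s) for s in shared) < 0.01

    def test_collapse_to_single_set(self):
        rng = np.random.default_rng(11)
        Y, A = rng.random((30, 4)), rng.random((30, 2))
        vp = b.varpart(Y, {"A": A, "B": None, "C": None, "D": None},
                       test_fractions=False)
        assert set(vp.fraction_table) == {"A"}
        assert vp.fraction_table["A"] == pytest.approx(b.rda(Y, A).r2_adj, abs=1e-12)

    def test_three_set_collapse(self):
        rng = np.random.default_rng(12)
        Y = rng.random((40, 3))
        sets = {"A": rng.random((40, 2)), "B": rng.random((40, 2)),
                "C": rng.random((40, 1)), "D": None}
        vp = b.varpart(Y, sets, test_fractions=False)
        assert len(vp.fraction_table) == 7

    def test_fraction_sum_equals_full_model(self):
        rng = np.random.default_rng(13)
        Y = rng.random((50, 6))
        sets = {k: rng.random((50, 2)) for k in "ABCD"}
        vp = b.varpart(Y, sets, test_fractions=False)
        assert sum(vp.fraction_table.values()) == pytest.approx(
            vp.full_model_r2_adj, abs=1e-12)
        assert vp.residual == pytest.approx(1 - vp.full_model_r2_adj, abs=1e-12)

    def test_duplicated_set_has_zero_unique_fraction(self):
        rng = np.random.default_rng(14)
        Y = rng.random((40, 4))
        A = rng.random((40, 2))
        vp = b.varpart(Y, {"A": A, "B": A.copy(), "C": None, "D": None},
                       test_fractions=False)
        assert vp.fraction_table["A"] == pytest.approx(0.0, abs=1e-10)
        assert vp.fraction_table["B"] == pytest.approx(0.0, abs=1e-10)
        assert vp.fraction_table["A&B"] == pytest.approx(b.rda(Y, A).r2_adj, abs=1e-10)

    def test_unadjusted_fractions_nonnegative(self):
        # recompute the partition on raw (unadjusted) R2: every fraction >= 0
        rng = np.random.default_rng(15)
        n = 60
        Y = rng.random((n, 4))
        sets = {"A": rng.random((n, 2)), "B": rng.random((n, 2))}
        from itertools import combinations
        names = sorted(sets)
        subsets = [tuple(c) for r in (1, 2) for c in combinations(names, r)]
        f = {s: b.rda(Y, [sets[k] for k in s]).r2 for s in subsets}
        uniq_a = f[("A", "B")] - f[("B",)]
        uniq_b = f[("A", "B")] - f[("A",)]
        shared = f[("A",)] + f[("B",)] - f[("A", "B")]
        assert uniq_a >= -1e-12 and uniq_b >= -1e-12
        assert uniq_a + uniq_b + shared == pytest.approx(f[("A", "B")], abs=1e-12)


class TestAnovaPermutation:
    def test_p_floor_with_overwhelming_effect(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 2))
        Y = X @ rng.random((2, 4)) * 10 + 0.01 * rng.standard_normal((30, 4))
        f, p = b.anova_permutation(Y, X, n_perm=99, seed=1)
        assert p == pytest.approx(1.0 / 100.0)

    def test_partial_test_controls_covariable(self):
        rng = np.random.default_rng(17)
        n = 50
        Z = rng.standard_normal((n, 2))
        Y = Z @ rng.random((2, 4)) * 5 + rng.standard_normal((n, 4))
        X = rng.standard_normal((n, 2))  # unrelated given Z
        _, p = b.anova_permutation(Y, X, Z, n_perm=199, seed=2)
        assert p > 0.05

    def test_power_with_strong_effect(self):
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(300 + trial)
            X = rng.standard_normal((50, 2))
            Y = X @ rng.standard_normal((2, 5)) + rng.standard_normal((50, 5))
            _, p = b.anova_permutation(Y, X, n_perm=199, seed=trial)
            hits += p <= 0.005
        assert hits >= 19

    def test_low_n_perm_rejected(self):
        rng = np.random.default_rng(18)
        with pytest.raises(ValueError):
            b.anova_permutation(rng.random((10, 2)), rng.random((10, 1)), n_perm=10)


class TestPredictFitted:
    def test_perfect_and_orthogonal_limits(self):
        rng = np.random.default_rng(19)
        Y = rng.random((15, 3))
        pred = b.predict_fitted(Y, Y.copy())
        assert np.allclose(pred, Y - Y.mean(axis=0), atol=1e-10)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(20)
        Y, X = rng.random((25, 6)), rng.random((25, 3))
        assert np.allclose(b.predict_fitted(Y, X), hat_matrix_fit(Y, X), atol=1e-10)
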