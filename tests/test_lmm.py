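"""REML engine: closed-form oracles, likelihood identities, BLUP shrinkage."""

import numpy as np
import pytest

from semifieldgp import ConfigurationError, MixedLMM, RandomTerm, StructureError


def one_way(g=10, r=5, su=1.0, se=0.5, seed=1):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(su), g)
    y = 2.0 + np.repeat(u, r) + rng.normal(0, np.sqrt(se), g * r)
    X = np.ones((g * r, 1))
    Z = np.kron(np.eye(g), np.ones((r, 1)))
    return y, X, Z


class TestRemlOracle:
    @pytest.mark.parametrize("g,r,seed", [(10, 5, 1), (8, 4, 2), (20, 3, 3)])
    def test_balanced_one_way_matches_anova_reml(self, g, r, seed):
        """On balanced one-way data REML equals the mean-squares closed form."""
        y, X, Z = one_way(g, r, seed=seed)
        res = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        ybar = y.reshape(g, r).mean(1)
        msb = r * np.sum((ybar - y.mean()) ** 2) / (g - 1)
        mse = np.sum((y.reshape(g, r) - ybar[:, None]) ** 2) / (g * (r - 1))
        assert res.converged
        assert res.params["u"] == pytest.approx(max((msb - mse) / r, 0.0), abs=1e-6)
        assert res.params["residual"] == pytest.approx(mse, abs=1e-6)

    def test_constant_response_all_floored(self):
        y = np.full(40, 3.0)
        X = np.ones((40, 1))
        Z = np.kron(np.eye(8), np.ones((5, 1)))
        res = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        assert (res.params <= res.floor * (1 + 1e-6)).all()

    def test_simulated_recovery_within_3se(self):
        """y = Zu + e at n=500 recovers the generating components."""
        y, X, Z = one_way(g=100, r=5, su=1.0, se=1.0, seed=3)
        res = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        assert res.converged
        assert abs(res.params["u"] - 1.0) <= 3 * res.bse["u"]
        assert abs(res.params["residual"] - 1.0) <= 3 * res.bse["residual"]


class TestLoglik:
    def test_em_trace_nondecreasing(self):
        y, X, Z = one_way(12, 4, seed=5)
        res = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        lls = res.loglik_trace()
        steps = [t["step"] for t in res.trace]
        for i in range(1, len(lls)):
            if steps[i] == "em":
                assert lls[i] >= lls[i - 1] - 1e-7

    def test_optimality_against_perturbation(self):
        y, X, Z = one_way(10, 5, seed=9)
        m = MixedLMM(y, X, [RandomTerm("u", Z)])
        res = m.fit()
        star = res.params.to_numpy()
        for bump in ([1.2, 1.0], [0.8, 1.0], [1.0, 1.2], [1.0, 0.8]):
            assert res.loglike >= m.profile_loglik(star * np.array(bump)) - 1e-9

    def test_matches_error_contrast_density(self):
        """3-observation toy: the reported value equals the density of an
        orthonormal error-contrast projection of y (brute-force oracle)."""
        y = np.array([1.0, 2.0, 4.0])
        X = np.ones((3, 1))
        Z = np.eye(3)
        K = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        m = MixedLMM(y, X, [RandomTerm("u", Z, K)])
        vcs = np.array([0.7, 0.4])
        V = 0.7 * K + 0.4 * np.eye(3)
        # orthonormal basis of the null space of X'
        q, _ = np.linalg.qr(np.column_stack([X, np.eye(3)]))
        A = q[:, 1:3]
        Ay = A.T @ y
        AVA = A.T @ V @ A
        brute = (
            -0.5 * (2 * np.log(2 * np.pi) + np.linalg.slogdet(AVA)[1]
                    + Ay @ np.linalg.solve(AVA, Ay))
        )
        assert m.profile_loglik(vcs) == pytest.approx(brute, abs=1e-10)

    def test_scale_equivariance(self):
        """Scaling y by c scales the variance components by c^2."""
        y, X, Z = one_way(10, 5, seed=11)
        res1 = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        res2 = MixedLMM(3.0 * y, X, [RandomTerm("u", Z)]).fit()
        assert np.allclose(res2.params, 9.0 * res1.params, rtol=1e-4)

    def test_wrong_vc_length_rejected(self):
        y, X, Z = one_way(5, 3)
        m = MixedLMM(y, X, [RandomTerm("u", Z)])
        with pytest.raises(ConfigurationError):
            m.profile_loglik([1.0, 1.0, 1.0])


class TestBlup:
    def test_two_group_shrinkage_oracle(self):
        """Single identity-kernel term: BLUP is the closed-form shrinkage
        n_i ybar_i su2 / (n_i su2 + se2) on centred group means."""
        y = np.array([3.0, 5.0, 4.0, -2.0, -4.0])
        X = np.ones((5, 1))
        Z = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1.0]])
        m = MixedLMM(y, X, [RandomTerm("u", Z)])
        su2, se2 = 2.0, 1.0
        sol = m.solve([su2, se2])
        mu = sol.fixed_effects.iloc[0]
        for i, (n_i, ybar) in enumerate([(3, 4.0), (2, -3.0)]):
            expect = n_i * (ybar - mu) * su2 / (n_i * su2 + se2)
            assert sol.blups["u"].iloc[i] == pytest.approx(expect, abs=1e-10)

    def test_identity_kernel_unobserved_level_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        Z = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0.0]])  # level 2 unobserved
        sol = MixedLMM(y, X, [RandomTerm("u", Z)]).solve([1.0, 1.0])
        assert sol.blups["u"].iloc[2] == 0.0

    def test_kernel_duplicate_levels_equal_blups(self):
        """Levels perfectly correlated through the kernel get equal BLUPs,
        observed or not."""
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 12)
        X = np.ones((12, 1))
        Z = np.zeros((12, 3))
        Z[:6, 0] = 1
        Z[6:, 1] = 1
        K = np.array([[1.0, 0.2, 1.0], [0.2, 1.0, 0.2], [1.0, 0.2, 1.0]])
        sol = MixedLMM(y, X, [RandomTerm("u", Z, K)]).solve([1.5, 1.0])
        assert sol.blups["u"].iloc[2] == pytest.approx(sol.blups["u"].iloc[0])

    def test_negative_vcs_rejected(self):
        y, X, Z = one_way(5, 3)
        with pytest.raises(ConfigurationError):
            MixedLMM(y, X, [RandomTerm("u", Z)]).solve([-1.0, 1.0])


class TestStructureChecks:
    def test_non_psd_kernel_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(StructureError):
            RandomTerm("u", np.eye(2), K)

    def test_kernel_dimension_mismatch(self):
        with pytest.raises(StructureError):
            RandomTerm("u", np.ones((4, 2)), np.eye(3))

    def test_permutation_equivariance(self):
        y, X, Z = one_way(8, 4, seed=13)
        res1 = MixedLMM(y, X, [RandomTerm("u", Z)]).fit()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        res2 = MixedLMM(y[perm], X[perm], [RandomTerm("u", Z[perm])]).fit()
        assert np.allclose(res1.params, res2.params, atol=1e-10)

    def test_rank_deficient_fixed_design_dropped_first_occurrence(self):
        y, X, Z = one_way(6, 4)
        X2 = np.column_stack([X, X, np.arange(24.0)])
        m = MixedLMM(y, X2, [RandomTerm("u", Z)], fixed_names=["a", "b", "c"])
        assert m.dropped_fixed == ["b"]

    def test_non_convergence_flagged_not_silent(self):
        y, X, Z = one_way(10, 5, seed=3)
        res = MixedLMM(y, X, [RandomTerm("u", Z)]).fit(maxiter=3)
        assert not res.converged
        assert res.bse.isna().all()


class TestKernelRecovery:
    """Seeded simulations per covariance kind recover generating components."""

    @pytest.mark.parametrize("kind", ["grm", "spatial", "block"])
    def test_recovery_within_3se(self, kind, toy_grm, toy_layout):
        rng = np.random.default_rng(17)
        n = 1000
        if kind == "grm":
            K = np.kron(np.eye(4), toy_grm.values)  # 48 levels
        elif kind == "spatial":
            from semifieldgp import build_s_knn

            K = np.kron(np.eye(2), build_s_knn(toy_layout, 5).S)  # 60 levels
        else:
            K = np.kron(np.eye(2), np.kron(np.eye(2), toy_grm.values))
        q = K.shape[0]
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        L = np.linalg.cholesky(K + 1e-8 * np.eye(q))
        su2, se2 = 1.0, 1.0
        u = L @ rng.standard_normal(q) * np.sqrt(su2)
        y = 1.0 + Z @ u + rng.standard_normal(n) * np.sqrt(se2)
        res = MixedLMM(y, np.ones((n, 1)), [RandomTerm("u", Z, K)]).fit()
        assert res.converged
        assert abs(res.params["u"] - su2) <= 3 * res.bse["u"]
        assert abs(res.params["residual"] - se2) <= 3 * res.bse["residual"]
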