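"""PLSC core: cross-covariance, SVD, permutations, bootstrap, scores."""

import numpy as np
import pytest

from ecplsc import (
    AlignmentError,
    ConfigurationError,
    ValidationError,
    aging_score,
    bootstrap_stability,
    build_design,
    compute_scores,
    cross_covariance,
    fit_plsc,
    generate_feature_matrix,
    permutation_test,
    plsc_svd,
    random_effect,
    threshold_saliences,
)


class TestCrossCovariance:
    def test_self_correlation_is_one(self, default_cohort, default_design):
        """A feature column equal to a design column correlates at exactly 1."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((128, 5))
        X[:, 2] = default_design.values[:, 0]  # z(age)
        R = cross_covariance(X, default_design)
        assert R[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_correlation(self):
        """4x2 X, 4x1 standardized Y of small integers vs the direct formula."""
        X = np.array([[1.0, 4.0], [2.0, 3.0], [3.0, 1.0], [4.0, 2.0]])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        yz = (y - y.mean()) / y.std(ddof=1)
        R = cross_covariance(X, yz[:, None])
        for j in range(2):
            x = X[:, j]
            r_hand = np.corrcoef(x, y)[0, 1]
            assert R[0, j] == pytest.approx(r_hand, abs=1e-12)

    def test_null_entries_bounded(self):
        """Independent X and Y at n=10000: every correlation-scale entry small."""
        rng = np.random.default_rng(42)
        n = 10_000
        X = rng.standard_normal((n, 379))
        Y = rng.standard_normal((n, 6))
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        assert np.abs(cross_covariance(X, Y)).max() < 0.05

    def test_misaligned_subjects_rejected(self, default_cohort, default_design):
        import pandas as pd

        X = pd.DataFrame(
            np.random.default_rng(0).standard_normal((128, 4)),
            index=[f"other-{i}" for i in range(128)],
        )
        with pytest.raises(AlignmentError):
            cross_covariance(X, default_design)

    def test_constant_region_named(self, default_design):
        import pandas as pd

        X = pd.DataFrame(
            np.random.default_rng(0).standard_normal((128, 3)),
            columns=["r0", "flat", "r2"],
            index=default_design.subject_ids,
        )
        X["flat"] = 1.0
        with pytest.raises(ValidationError, match="flat"):
            cross_covariance(X, default_design)


class TestPlscSvd:
    def test_rank_one_factorization(self):
        rng = np.random.default_rng(1)
        u0 = rng.standard_normal(6)
        u0 /= np.linalg.norm(u0)
        v0 = rng.standard_normal(15)
        v0 /= np.linalg.norm(v0)
        U, s, V = plsc_svd(3.0 * np.outer(u0, v0))
        assert s[0] == pytest.approx(3.0, abs=1e-10)
        assert np.all(s[1:] < 1e-10)
        assert abs(U[:, 0] @ u0) == pytest.approx(1.0, abs=1e-10)
        assert abs(V[:, 0] @ v0) == pytest.approx(1.0, abs=1e-10)

    def test_frobenius_energy_identity(self):
        rng = np.random.default_rng(2)
        R = rng.standard_normal((6, 40))
        _, s, _ = plsc_svd(R)
        assert np.sum(s**2) == pytest.approx(np.linalg.norm(R) ** 2, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        """3x5 seeded matrix: U, s, V from eigendecompositions of RR^T, R^T R."""
        rng = np.random.default_rng(7)
        R = rng.standard_normal((3, 5))
        U, s, V = plsc_svd(R)
        lam_l, U_o = np.linalg.eigh(R @ R.T)
        lam_r, V_o = np.linalg.eigh(R.T @ R)
        np.testing.assert_allclose(s, np.sqrt(lam_l[::-1].clip(0)), atol=1e-8)
        np.testing.assert_allclose(
            s, np.sqrt(lam_r[::-1][:3].clip(0)), atol=1e-8
        )
        for k in range(3):
            assert abs(U[:, k] @ U_o[:, ::-1][:, k]) == pytest.approx(1, abs=1e-8)
            assert abs(V[:, k] @ V_o[:, ::-1][:, k]) == pytest.approx(1, abs=1e-8)

    def test_orthonormality(self):
        rng = np.random.default_rng(3)
        U, s, V = plsc_svd(rng.standard_normal((6, 30)))
        np.testing.assert_allclose(U.T @ U, np.eye(6), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(6), atol=1e-10)

    def test_non_finite_rejected(self):
        R = np.ones((2, 3))
        R[0, 0] = np.nan
        with pytest.raises(ValidationError):
            plsc_svd(R)


class TestPermutationTest:
    def test_p_floor_is_one_over_nperm_plus_one(self, default_cohort, default_design):
        """Strong planted effect: p1 hits the add-one floor exactly."""
        eff = random_effect(60, 8.0, seed=5)
        X = generate_feature_matrix(default_cohort, [eff], noise_sd=0.5, seed=5)
        p = permutation_test(X, default_design, n_permutations=99, seed=0)
        assert p[0] == pytest.approx(1 / 100)

    def test_schemes_agree_on_first_component(self, default_cohort, default_design):
        """Deflation changes nothing for rank 1 by construction."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((128, 50))
        p_simple = permutation_test(
            X, default_design, n_permutations=200, seed=3, scheme="simple"
        )
        p_deflate = permutation_test(
            X, default_design, n_permutations=200, seed=3, scheme="deflate"
        )
        assert p_simple[0] == p_deflate[0]

    def test_deterministic_given_seed(self, default_cohort, default_design):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((128, 30))
        a = permutation_test(X, default_design, n_permutations=50, seed=11)
        b = permutation_test(X, default_design, n_permutations=50, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_invalid_count_rejected(self, default_design):
        with pytest.raises(ConfigurationError):
            permutation_test(
                np.ones((128, 2)) + np.arange(128)[:, None],
                default_design, n_permutations=0, seed=0,
            )


class TestBootstrap:
    def test_ratio_sign_matches_salience_sign(self, default_cohort, default_design):
        eff = random_effect(40, 5.0, seed=6)
        X = generate_feature_matrix(default_cohort, [eff], noise_sd=1.0, seed=6)
        res = fit_plsc(X, default_design, n_permutations=10, n_bootstrap=100, seed=2)
        nz = np.abs(res.br_V) > 0
        assert np.all(np.sign(res.br_V[nz]) == np.sign(res.V[nz]))

    def test_planted_top_regions_stable(self, default_cohort, default_design):
        """Strength-5 effect, unit noise: the 10 largest-|loading| planted
        regions all exceed |BR| > 2 in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            eff = random_effect(379, 5.0, seed=3000 + seed)
            X = generate_feature_matrix(
                default_cohort, [eff], noise_sd=1.0, seed=seed
            )
            boot = bootstrap_stability(
                X, default_design, n_bootstrap=200, seed=seed
            )
            top10 = np.argsort(-np.abs(eff.brain_pattern))[:10]
            if np.all(np.abs(boot["br_V"][top10, 0]) > 2):
                hits += 1
        assert hits >= 9

    def test_se_floor_guard_on_degenerate_data(self, default_cohort, default_design):
        """With a single region the brain salience is identically +-1 across
        resamples: the SE floor engages, is flagged, and BRs stay finite."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((128, 1))
        boot = bootstrap_stability(X, default_design, n_bootstrap=50, seed=0)
        assert boot["floored_V"].any()
        assert np.all(np.isfinite(boot["br_V"]))
        assert np.all(np.isfinite(boot["br_U"]))

    def test_constant_design_column_exhausts_redraws(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 6))
        Y[:, 1] = 0.0  # constant in every possible resample
        with pytest.raises(ValidationError, match="redraws"):
            bootstrap_stability(X, Y, n_bootstrap=5, seed=0)

    def test_redraw_recovers_from_rare_constant_resamples(self):
        """A rare binary level forces redraws but the bootstrap completes."""
        rng = np.random.default_rng(2)
        n = 8
        X = rng.standard_normal((n, 4))
        flag = np.zeros(n)
        flag[0] = 1.0  # single carrier: ~35% of resamples miss it
        Y = np.column_stack([rng.standard_normal((n, 5)), flag])
        boot = bootstrap_stability(X, Y, n_bootstrap=50, seed=3)
        assert np.all(np.isfinite(boot["br_V"]))


class TestThresholding:
    def test_all_zero_ratios_give_empty_table(self):
        table = threshold_saliences(np.zeros((10, 2)))
        assert table.empty

    def test_threshold_is_strict(self):
        br = np.array([[2.0], [2.0001], [-2.0]])
        table = threshold_saliences(br, br_threshold=2.0)
        assert len(table) == 1
        assert table.iloc[0]["region"] == "region_001"

    def test_signs_and_selection(self):
        br = np.array([3.0, -2.5, 1.9])
        table = threshold_saliences(br, region_ids=["a", "b", "c"])
        assert table["region"].tolist() == ["a", "b"]
        assert table["sign"].tolist() == ["+", "-"]


class TestScoresAndAging:
    def test_indicator_salience_projects_single_column(self, default_cohort,
                                                       default_design):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((128, 5))
        V = np.zeros((5, 1))
        V[3, 0] = 1.0
        U = np.zeros((6, 1))
        U[0, 0] = 1.0
        Lx, Ly = compute_scores(X, default_design, U, V)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(Lx[:, 0], Xz[:, 3], atol=1e-12)
        np.testing.assert_allclose(Ly[:, 0], default_design.values[:, 0], atol=1e-12)

    def test_first_component_maximizes_covariance(self, small_cohort):
        """cov(Lx1, Ly1) beats 1000 random unit direction pairs."""
        eff = random_effect(20, 2.0, seed=14)
        X = generate_feature_matrix(small_cohort, [eff], noise_sd=0.5, seed=14)
        Y = build_design(small_cohort)
        R = cross_covariance(X, Y)
        U, s, V = plsc_svd(R)
        Lx, Ly = compute_scores(X, Y, U, V)
        n = len(small_cohort)
        best = (Lx[:, 0] @ Ly[:, 0]) / (n - 1)
        rng = np.random.default_rng(15)
        Xz = (X.values - X.values.mean(0)) / X.values.std(0, ddof=1)
        for _ in range(1000):
            w = rng.standard_normal(20)
            w /= np.linalg.norm(w)
            z = rng.standard_normal(6)
            z /= np.linalg.norm(z)
            cand = ((Xz @ w) @ (Y.values @ z)) / (n - 1)
            assert best >= cand - 1e-12

    def test_latent_variance_identity(self, default_design):
        """Column variances of Lx equal diag(V^T S V) for sample covariance S."""
        rng = np.random.default_rng(16)
        X = rng.standard_normal((128, 12))
        R = cross_covariance(X, default_design)
        U, s, V = plsc_svd(R)
        Lx, _ = compute_scores(X, default_design, U, V)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        S = np.cov(Xz, rowvar=False, ddof=1)
        np.testing.assert_allclose(
            Lx.var(axis=0, ddof=1), np.diag(V.T @ S @ V), atol=1e-10
        )

    def test_aging_score_hand_example(self):
        """Two subjects with Y^age rows (1,0,0), (0,1,1) and U^age (0.5,0.3,0.2)
        score (0.5, 0.5)."""
        Y = np.zeros((2, 6))
        Y[0, 0] = 1.0           # age
        Y[1, 3] = Y[1, 4] = 1.0  # the two age interactions
        U = np.zeros((6, 2))
        U[0, 0], U[3, 0], U[4, 0] = 0.5, 0.3, 0.2
        sc = aging_score(Y, U, component=1)
        np.testing.assert_allclose(sc.values, [0.5, 0.5], atol=1e-14)

    def test_aging_score_ignores_non_age_saliences(self, default_design):
        U = np.random.default_rng(17).standard_normal((6, 2))
        base = aging_score(default_design, U, component=2)
        U2 = U.copy()
        U2[[1, 2, 5], :] = 99.0  # non-age rows are irrelevant
        np.testing.assert_array_equal(
            base.values, aging_score(default_design, U2, component=2).values
        )

    def test_zero_age_saliences_give_zero_scores(self, default_design):
        U = np.zeros((6, 1))
        U[1, 0] = 1.0  # apoe4 only
        assert np.all(aging_score(default_design, U, 1).values == 0)

    def test_aging_score_equals_ly_when_non_age_saliences_vanish(
        self, default_design
    ):
        U = np.zeros((6, 1))
        U[[0, 3, 4], 0] = np.array([0.6, 0.64, 0.48]) / np.linalg.norm(
            [0.6, 0.64, 0.48]
        )
        Ly = default_design.values @ U
        sc = aging_score(default_design, U, 1)
        np.testing.assert_allclose(sc.values, Ly[:, 0], atol=1e-14)


class TestFitPlsc:
    def test_result_invariants(self, default_cohort, default_design):
        eff = random_effect(40, 4.0, seed=20)
        X = generate_feature_matrix(default_cohort, [eff], noise_sd=1.0, seed=20)
        res = fit_plsc(X, default_design, n_permutations=50, n_bootstrap=50, seed=4)
        assert np.all(np.diff(res.singular_values) <= 1e-12)
        assert np.all((res.p_values > 0) & (res.p_values <= 1))
        np.testing.assert_allclose(res.U.T @ res.U, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(res.V.T @ res.V, np.eye(6), atol=1e-8)
        # scores reproducible from stored saliences
        Lx, Ly = compute_scores(X, default_design, res.U, res.V)
        np.testing.assert_allclose(res.Lx, Lx, atol=1e-12)
        np.testing.assert_allclose(res.Ly, Ly, atol=1e-12)

    def test_column_scale_invariance(self, default_cohort, default_design):
        """Doubling an X column before internal z-scoring changes nothing."""
        eff = random_effect(30, 3.0, seed=21)
        X = generate_feature_matrix(default_cohort, [eff], noise_sd=1.0, seed=21)
        X2 = X.copy()
        X2.iloc[:, 7] *= 2.0
        a = fit_plsc(X, default_design, n_permutations=30, n_bootstrap=30, seed=5)
        b = fit_plsc(X2, default_design, n_permutations=30, n_bootstrap=30, seed=5)
        np.testing.assert_allclose(a.singular_values, b.singular_values, atol=1e-12)
        np.testing.assert_allclose(a.V, b.V, atol=1e-10)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_allclose(a.br_V, b.br_V, atol=1e-8)

    def test_permutation_results_independent_of_bootstrap_count(
        self, default_cohort, default_design
    ):
        """Child seed streams: changing n_bootstrap leaves p-values untouched."""
        rng = np.random.default_rng(22)
        X = rng.standard_normal((128, 20))
        a = fit_plsc(X, default_design, n_permutations=50, n_bootstrap=20, seed=6)
        b = fit_plsc(X, default_design, n_permutations=50, n_bootstrap=60, seed=6)
        np.testing.assert_array_equal(a.p_values, b.p_values)
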