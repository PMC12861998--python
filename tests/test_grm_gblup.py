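import numpy as np
import pytest

from gainsim import grm_gblup as gg
from gainsim.genome_founders import ConfigurationError

from .conftest import toy_gblup_data
from .oracles import (
    conditional_mean_prediction,
    one_way_reml_closed_form,
    restricted_loglik_oracle,
)


class TestKernels:
    def test_centering_zeroes_column_means(self, small_founders):
        M, xbar = gg.code_and_center(small_founders)
        assert np.all(np.abs(M.mean(axis=0)) < 1e-10)
        assert M.shape[1] == len(small_founders.gmap.snp_indices)

    def test_monomorphic_marker_column_is_zero(self):
        G = np.array([[1.0, 1.0], [1.0, -1.0]])
        M = G - G.mean(axis=0)
        assert np.allclose(M[:, 0], 0.0)

    def test_hand_centered_example(self):
        # genotypes (1, −1): mean 0, column unchanged
        G = np.array([[1.0], [-1.0]])
        M = G - G.mean(axis=0)
        np.testing.assert_allclose(M, [[1.0], [-1.0]])

    def test_additive_grm_hand_example(self):
        M = np.array([[1.0], [-1.0]])
        Ga = gg.additive_grm(M)
        np.testing.assert_allclose(Ga, [[1.0, -1.0], [-1.0, 1.0]])

    def test_duplicate_individuals_share_rows(self, small_founders):
        M, _ = gg.code_and_center(small_founders)
        M2 = np.vstack([M, M[:1]])
        Ga = gg.additive_grm(M2)
        np.testing.assert_allclose(Ga[0], Ga[-1])
        assert Ga[0, 0] == pytest.approx(Ga[-1, -1])

    def test_grm_rows_sum_to_zero(self, small_founders):
        M, _ = gg.code_and_center(small_founders)
        Ga = gg.additive_grm(M)
        assert np.all(np.abs(Ga @ np.ones(Ga.shape[0])) < 1e-8)
        assert np.trace(Ga) / Ga.shape[0] == pytest.approx(1.0)

    def test_epistatic_grm_identity_case(self):
        I = np.eye(4)
        Gaa, Gaa_norm = gg.epistatic_grm(I)
        np.testing.assert_allclose(Gaa, I)
        np.testing.assert_allclose(Gaa_norm, I)

    def test_epistatic_grm_hand_example(self):
        Ga = np.array([[1.0, -1.0], [-1.0, 1.0]])
        Gaa, Gaa_norm = gg.epistatic_grm(Ga)
        np.testing.assert_allclose(Gaa, np.ones((2, 2)))
        np.testing.assert_allclose(Gaa_norm, Gaa)

    def test_epistatic_mean_diagonal_is_one(self, small_founders):
        ks = gg.build_kernels(small_founders)
        assert np.diag(ks.Gaa_norm).mean() == pytest.approx(1.0, abs=1e-10)

    def test_empty_snp_set_raises(self, small_founders):
        with pytest.raises(ConfigurationError):
            gg.code_and_center(small_founders, np.array([], dtype=int))


class TestREML:
    def test_boundary_recovery_without_epistasis(self):
        # data generated with σ_aa² = 0: the component shrinks to the floor
        y, Ga, Gaa = toy_gblup_data(n=150, seed=3, sa2=1.5, saa2=0.0, se2=0.5)
        fit = gg.fit_reml(y, Ga, Gaa)
        assert fit.sigma_aa2 < 0.05 * y.var()
        assert fit.sigma_a2 > 0.2

    def test_matches_grid_search_oracle(self):
        y, Ga, Gaa = toy_gblup_data(n=60, seed=1)
        fit = gg.fit_reml(y, Ga, Gaa)
        ll_fit = restricted_loglik_oracle(
            y, [Ga, Gaa], np.array([fit.sigma_a2, fit.sigma_aa2, fit.sigma_e2])
        )
        from .oracles import grid_search_reml

        _, ll_grid = grid_search_reml(y, [Ga, Gaa], n_points=9)
        assert ll_fit >= ll_grid - 1e-3

    def test_balanced_one_way_closed_form(self):
        # group-mean kernel: the model reduces to classical one-way REML
        rng = np.random.default_rng(7)
        g, r = 12, 6
        groups = np.repeat(np.arange(g), r)
        K = (groups[:, None] == groups[None, :]).astype(float)
        y = rng.standard_normal(g)[groups] * 1.3 + rng.standard_normal(g * r)
        fit = gg.fit_reml(y, K, None, tol=1e-10)
        sg2, se2 = one_way_reml_closed_form(y, groups)
        assert fit.sigma_a2 == pytest.approx(sg2, rel=1e-3, abs=1e-6)
        assert fit.sigma_e2 == pytest.approx(se2, rel=1e-3)

    def test_translation_invariance(self):
        y, Ga, Gaa = toy_gblup_data(n=80, seed=5)
        f0 = gg.fit_reml(y, Ga, Gaa)
        f1 = gg.fit_reml(y + 10.0, Ga, Gaa)
        assert f1.mu == pytest.approx(f0.mu + 10.0, abs=1e-4)
        assert f1.sigma_a2 == pytest.approx(f0.sigma_a2, rel=1e-4)
        assert f1.sigma_e2 == pytest.approx(f0.sigma_e2, rel=1e-4)
        np.testing.assert_allclose(f1.blup_a, f0.blup_a, atol=1e-5)

    def test_pure_noise_shrinks_blups(self):
        rng = np.random.default_rng(11)
        y, Ga, Gaa = toy_gblup_data(n=120, seed=8, sa2=0.0, saa2=0.0, se2=1.0)
        fit = gg.fit_reml(y, Ga, Gaa)
        assert np.abs(fit.total_blup).max() < 0.25 * y.std()

    def test_total_blup_is_sum_of_components(self):
        y, Ga, Gaa = toy_gblup_data(n=60, seed=2)
        fit = gg.fit_reml(y, Ga, Gaa)
        np.testing.assert_array_equal(fit.total_blup, fit.blup_a + fit.blup_aa)
        assert min(fit.sigma_a2, fit.sigma_aa2, fit.sigma_e2) >= 0


class TestProjection:
    def test_self_projection_returns_fitted_blups(self):
        y, Ga, Gaa = toy_gblup_data(n=60, seed=4)
        fit = gg.fit_reml(y, Ga, Gaa)
        yhat, g_a, g_aa = gg.project_to_shelf(fit, Ga, Gaa, Ga, Gaa)
        np.testing.assert_allclose(g_a, fit.blup_a, atol=1e-6)
        np.testing.assert_allclose(yhat, fit.mu + fit.total_blup, atol=1e-6)

    def test_zero_kinship_projects_prior_mean(self):
        y, Ga, Gaa = toy_gblup_data(n=40, seed=6)
        fit = gg.fit_reml(y, Ga, Gaa)
        Z = np.zeros((40, 7))
        yhat, _, _ = gg.project_to_shelf(fit, Z, Z, Ga, Gaa)
        np.testing.assert_allclose(yhat, fit.mu, atol=1e-8)

    def test_matches_conditional_mean_oracle(self):
        # projection ≡ joint-Gaussian conditional mean (union refit with
        # missing shelf phenotypes)
        y, Ga, Gaa = toy_gblup_data(n=90, seed=9)
        test, shelf = np.arange(60), np.arange(60, 90)
        Ga_tt, Gaa_tt = Ga[np.ix_(test, test)], Gaa[np.ix_(test, test)]
        Ga_ts, Gaa_ts = Ga[np.ix_(test, shelf)], Gaa[np.ix_(test, shelf)]
        fit = gg.fit_reml(y[test], Ga_tt, Gaa_tt)
        yhat, _, _ = gg.project_to_shelf(fit, Ga_ts, Gaa_ts, Ga_tt, Gaa_tt)
        oracle = conditional_mean_prediction(
            y[test],
            Ga_tt,
            Gaa_tt,
            Ga_ts.T,
            Gaa_ts.T,
            np.array([fit.sigma_a2, fit.sigma_aa2, fit.sigma_e2]),
            fit.mu,
        )
        np.testing.assert_allclose(yhat, oracle, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        y, Ga, Gaa = toy_gblup_data(n=30, seed=10)
        fit = gg.fit_reml(y, Ga, Gaa)
        with pytest.raises(ConfigurationError):
            gg.project_to_shelf(fit, Ga[:10], Gaa[:10], Ga, Gaa)
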