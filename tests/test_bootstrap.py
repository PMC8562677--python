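"""Parametric bootstrap: components, the kernel map, draws, and the test."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utilitr import (GenerativeConfig, bootstrap_draw, estimate_components,
                     fit_q, heterogeneity_test, k_tilde, metropolis_search,
                     simulate)
from utilitr.bootstrap import (AsymptoticComponents, DegenerateContrastError,
                               block_sqrt, psd_sqrt)
from utilitr.cohorts import CohortData


@pytest.fixture(scope="module")
def biv_fit(bivariate_cohort):
    q_y, q_z = fit_q(bivariate_cohort, "y"), fit_q(bivariate_cohort, "z")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = metropolis_search(bivariate_cohort, q_y, q_z, chain_length=400,
                                sigma=0.25, seed=17)
    return q_y, q_z, fit


@pytest.fixture(scope="module")
def biv_components(bivariate_cohort, biv_fit):
    q_y, q_z, fit = biv_fit
    return estimate_components(bivariate_cohort, fit, q_y, q_z)


class TestMatrixRoots:
    def test_psd_sqrt_reconstructs(self, rng):
        A = rng.normal(size=(6, 6))
        M = A @ A.T
        R = psd_sqrt(M)
        np.testing.assert_allclose(R @ R, M, atol=1e-10)

    def test_block_sqrt_reconstructs_sigma(self, biv_components):
        c = biv_components
        L = c.sigma_root
        assert np.linalg.norm(L @ L.T - c.sigma) <= 1e-8 * np.linalg.norm(c.sigma)
        # upper-right block is exactly zero (lower-block-triangular root)
        assert np.max(np.abs(L[: c.q, c.q:])) == 0.0

    def test_block_sqrt_random_psd(self, rng):
        A = rng.normal(size=(9, 9))
        M = A @ A.T
        L = block_sqrt(M, 5)
        np.testing.assert_allclose(L @ L.T, M, atol=1e-9)


class TestComponents:
    def test_sigma_psd_and_influence_centering(self, biv_components):
        c = biv_components
        vals = np.linalg.eigvalsh(c.sigma)
        assert vals.min() >= -1e-10

    def test_duplicating_subjects_scales_bandwidth(self, bivariate_cohort,
                                                   biv_fit):
        q_y, q_z, fit = biv_fit
        comp = estimate_components(bivariate_cohort, fit, q_y, q_z)
        dup = CohortData(np.vstack([bivariate_cohort.X] * 2),
                         np.concatenate([bivariate_cohort.A] * 2),
                         np.concatenate([bivariate_cohort.Y] * 2),
                         np.concatenate([bivariate_cohort.Z] * 2))
        q_y2, q_z2 = fit_q(dup, "y"), fit_q(dup, "z")
        comp2 = estimate_components(dup, fit, q_y2, q_z2)
        ratio = comp2.bandwidth / comp.bandwidth
        # v_hat is almost unchanged (ddof effect only); h scales by 2^(-1/5)
        assert ratio == pytest.approx(2 ** (-0.2), rel=2e-3)

    def test_degenerate_contrast_raises(self, bivariate_cohort, biv_fit):
        q_y, q_z, fit = biv_fit
        flat = CohortData(np.zeros_like(bivariate_cohort.X) + 0.0,
                          bivariate_cohort.A, bivariate_cohort.Y,
                          bivariate_cohort.Z)
        # identical covariates make D_hat constant -> zero bandwidth
        with pytest.raises((DegenerateContrastError, np.linalg.LinAlgError)):
            q_y2 = fit_q(flat, "y")


class TestKTilde:
    def test_zero_arguments_give_zero_vector(self, biv_components):
        c = biv_components
        out = k_tilde(c, np.zeros(c.q1), np.zeros(c.q2), np.zeros(c.d))
        np.testing.assert_allclose(out, np.zeros_like(out), atol=1e-14)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
    def test_positive_degree_one_homogeneity(self, biv_components, seed, cscale):
        c = biv_components
        r = np.random.default_rng(seed)
        zy, zz, u = r.normal(size=c.q1), r.normal(size=c.q2), r.normal(size=c.d)
        k1 = k_tilde(c, zy, zz, u)
        kc = k_tilde(c, cscale * zy, cscale * zz, cscale * u)
        np.testing.assert_allclose(kc, cscale * k1, rtol=1e-9, atol=1e-12)

    def test_sign_evenness(self, biv_components, rng):
        """Negating all arguments leaves k~ unchanged (|t| is even)."""
        c = biv_components
        zy, zz, u = (rng.normal(size=c.q1), rng.normal(size=c.q2),
                     rng.normal(size=c.d))
        np.testing.assert_allclose(k_tilde(c, zy, zz, u),
                                   k_tilde(c, -zy, -zz, -u), atol=1e-12)

    def test_three_subject_hand_evaluation(self):
        """Term-by-term check of the kernel average on handcrafted pieces."""
        xb = np.array([[1.0, 0.5], [1.0, -1.0], [1.0, 2.0]])
        comp = AsymptoticComponents(
            n=3, theta=np.array([0.0, 0.0]), beta=np.array([1.0, 0.0]),
            sigma=np.eye(6), sigma_root=np.eye(6), info=np.eye(2),
            bandwidth=1.0, contrast_sd=1.0, q1=2, q2=2,
            x_behavior=xb, kernel=np.array([0.3, 0.2, 0.1]),
            sign_weight=np.array([0.5, -0.5, 1.0]),
            phi_y=2 * xb, phi_z=2 * xb,
            a_y=np.array([1.0, 2.0, -1.0]), a_z=np.array([0.5, 0.0, 1.5]),
            r_diff=np.array([1.0, -1.0, 2.0]),
            omega_dot=0.25 * xb)
        zy, zz, u = np.array([1.0, -1.0]), np.array([0.5, 0.5]), np.array([2.0, 0.0])
        t = (comp.a_y * (comp.phi_y @ zy) + comp.a_z * (comp.phi_z @ zz)
             + comp.r_diff * (comp.omega_dot @ u))
        denom = np.mean(comp.kernel)
        expected = np.zeros(2)
        for i in range(3):
            expected += (xb[i] * comp.sign_weight[i] * abs(t[i])
                         * comp.kernel[i])
        expected /= 3 * denom
        np.testing.assert_allclose(k_tilde(comp, zy, zz, u), expected, atol=1e-12)


class TestBootstrapDraw:
    def test_zero_sigma_gives_zero_draw(self, biv_components):
        import dataclasses
        c = dataclasses.replace(biv_components, sigma=np.zeros_like(
            biv_components.sigma), sigma_root=np.zeros_like(biv_components.sigma))
        draw = bootstrap_draw(c, seed=0)
        np.testing.assert_allclose(draw.U, 0.0, atol=1e-6)
        np.testing.assert_allclose(draw.B, 0.0, atol=1e-6)

    def test_same_seed_identical(self, biv_components):
        d1 = bootstrap_draw(biv_components, seed=11)
        d2 = bootstrap_draw(biv_components, seed=11)
        np.testing.assert_array_equal(d1.U, d2.U)
        np.testing.assert_array_equal(d1.B, d2.B)

    def test_minimizer_matches_dense_grid(self):
        """On a univariate-covariate instance (u 2-dim) the inner argmin
        agrees with a dense grid search over [-10, 10]^2."""
        cfg = GenerativeConfig(n=150, p=1, utility=(0.5, 0.2),
                               behavior=(1.0, 0.5), seed=2)
        c = simulate(cfg)
        q_y, q_z = fit_q(c, "y"), fit_q(c, "z")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = metropolis_search(c, q_y, q_z, chain_length=150,
                                    sigma=0.3, seed=3)
        comp = estimate_components(c, fit, q_y, q_z)
        rng = np.random.default_rng(4)
        z = comp.sigma_root @ rng.standard_normal(comp.r)
        zy, zz = z[:comp.q1], z[comp.q1:comp.q]

        def obj(u):
            return float(comp.beta @ k_tilde(comp, zy, zz, u))

        grid = np.linspace(-10, 10, 161)
        vals = np.array([[obj(np.array([a, b])) for b in grid] for a in grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        from utilitr.bootstrap import _minimize_u
        u_hat, f_hat, ok = _minimize_u(comp, zy, zz)
        assert f_hat <= vals[i, j] + 1e-6
        assert np.max(np.abs(u_hat - np.array([grid[i], grid[j]]))) < 0.25


class TestHeterogeneityTest:
    def test_zero_theta_slopes_give_p_one(self, bivariate_cohort, biv_fit):
        import dataclasses
        q_y, q_z, fit = biv_fit
        null_fit = dataclasses.replace(
            fit, theta=np.array([fit.theta[0], 0.0, 0.0]))
        test = heterogeneity_test(bivariate_cohort, null_fit, q_y, q_z,
                                  n_boot=100, seed=0)
        assert test.statistic == 0.0
        assert test.p_value == 1.0
        assert not test.reject

    def test_bootstrap_sds_stabilize(self, bivariate_cohort, biv_fit):
        """Half-sample coefficients of variation of the B~ SDs < 10%."""
        q_y, q_z, fit = biv_fit
        test = heterogeneity_test(bivariate_cohort, fit, q_y, q_z,
                                  n_boot=1000, seed=1)
        half = test.draws_B.shape[0] // 2
        sd1 = test.draws_B[:half].std(axis=0, ddof=1)
        sd2 = test.draws_B[half:].std(axis=0, ddof=1)
        cv = np.abs(sd1 - sd2) / (0.5 * (sd1 + sd2))
        assert np.max(cv) < 0.10

    def test_requires_minimum_draws(self, bivariate_cohort, biv_fit):
        q_y, q_z, fit = biv_fit
        with pytest.raises(ValueError):
            heterogeneity_test(bivariate_cohort, fit, q_y, q_z, n_boot=10)

    def test_studentized_variant(self, bivariate_cohort, biv_fit):
        q_y, q_z, fit = biv_fit
        plain = heterogeneity_test(bivariate_cohort, fit, q_y, q_z,
                                   n_boot=150, seed=4)
        stud = heterogeneity_test(bivariate_cohort, fit, q_y, q_z,
                                  n_boot=150, seed=4, studentized=True)
        assert 0.0 <= stud.p_value <= 1.0
        assert stud.statistic != plain.statistic  # scales differ

    def test_theta_se_exposed(self, bivariate_cohort, biv_fit):
        q_y, q_z, fit = biv_fit
        test = heterogeneity_test(bivariate_cohort, fit, q_y, q_z,
                                  n_boot=150, seed=2)
        assert test.theta_se.shape == (3,)
        assert np.all(test.theta_se > 0)
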