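"""Q-model fitting, contrasts, decision rules, and the influence expansion."""

import numpy as np
import pytest

from utilitr import (FixedUtility, GenerativeConfig, LogisticUtility,
                     TreatmentRule, fit_q, influence_basis, simulate,
                     weighted_contrast)
from utilitr.cohorts import CohortData
from utilitr.qmodels import RankError
from utilitr._utils import add_intercept


def _noiseless_cohort(n=400, seed=0):
    cfg = GenerativeConfig(n=n, utility=0.25, behavior=0.6,
                           noise_sd=1e-14, seed=seed)
    return cfg, simulate(cfg)


class TestFitQ:
    def test_noiseless_exact_recovery(self):
        """With eps = 0 the interaction block interpolates the truth exactly."""
        cfg, c = _noiseless_cohort()
        q = fit_q(c, "y")
        np.testing.assert_allclose(q.interaction, cfg.outcome_coefs_y, atol=1e-8)
        x = np.random.default_rng(1).normal(0, 0.5, size=(50, 5))
        np.testing.assert_allclose(q.contrast(x), 2 * add_intercept(x) @
                                   cfg.outcome_coefs_y, atol=1e-7)

    def test_constant_outcome_zero_contrast(self, fixed_cohort):
        c = CohortData(fixed_cohort.X, fixed_cohort.A,
                       np.full(fixed_cohort.n, 3.7), fixed_cohort.Z)
        q = fit_q(c, "y")
        assert np.max(np.abs(q.contrast(c.X))) < 1e-8

    def test_contrast_at_origin_within_sampling_error(self, fixed_cohort,
                                                      fixed_qmodels):
        """R_Y(0) = 4; the OLS estimate lies within 3 SEs of it."""
        q_y, _ = fixed_qmodels
        # var of 2*(intercept coef of interaction block)
        cov = q_y.sigma2 * q_y.gram_inv
        se = 2.0 * np.sqrt(cov[q_y.k, q_y.k])
        assert abs(q_y.contrast(np.zeros((1, 5)))[0] - 4.0) < 3 * se

    def test_rank_deficient_design_names_columns(self, fixed_cohort):
        X = fixed_cohort.X.copy()
        X[:, 3] = X[:, 2]  # duplicate a column
        c = CohortData(X, fixed_cohort.A, fixed_cohort.Y, fixed_cohort.Z)
        with pytest.raises(RankError, match="x"):
            fit_q(c, "y")

    def test_too_small_sample_rejected(self):
        cfg = GenerativeConfig(n=10, utility=0.25, behavior=0.6, seed=0)
        with pytest.raises(RankError):
            fit_q(simulate(cfg), "y")

    def test_prediction_differencing_identity(self, fixed_cohort, fixed_qmodels):
        q_y, _ = fixed_qmodels
        x = fixed_cohort.X[:25]
        diff = q_y.predict(x, 1.0) - q_y.predict(x, -1.0)
        np.testing.assert_allclose(diff, q_y.contrast(x), atol=1e-12)

    def test_feature_subset(self, fixed_cohort):
        q = fit_q(fixed_cohort, "y", features=[0, 1])
        assert q.params.size == 6
        assert q.column_names == ["const", "x1", "x2", "a", "a:x1", "a:x2"]

    def test_covariance_types_agree_under_homoscedasticity(self, fixed_qmodels):
        """Model-based and sandwich covariances of the interaction block are
        close when the errors really are homoscedastic Gaussians."""
        q_y, _ = fixed_qmodels
        v_model = np.diag(q_y.covariance("nonrobust"))
        v_hc0 = np.diag(q_y.covariance("HC0"))
        assert np.all(np.abs(v_hc0 / v_model - 1.0) < 0.5)
        with pytest.raises(ValueError):
            q_y.covariance("HC3")

    def test_serialization(self, fixed_qmodels):
        q_y, _ = fixed_qmodels
        d = q_y.to_dict()
        assert set(d["terms"]) == set(q_y.column_names)


class TestTreatmentRule:
    def test_omega_endpoints_reduce_to_single_contrast(self, fixed_cohort,
                                                       fixed_qmodels):
        q_y, q_z = fixed_qmodels
        x = fixed_cohort.X[:40]
        np.testing.assert_allclose(
            weighted_contrast(TreatmentRule(FixedUtility(1.0), q_y, q_z), x),
            q_y.contrast(x))
        np.testing.assert_allclose(
            weighted_contrast(TreatmentRule(FixedUtility(0.0), q_y, q_z), x),
            q_z.contrast(x))

    def test_tie_decision_is_plus_one(self, fixed_qmodels):
        q_y, q_z = fixed_qmodels
        rule = TreatmentRule(FixedUtility(0.5), q_y, q_z)
        assert np.all(rule.decide(np.zeros((1, 5))) in (-1.0, 1.0))
        # force an exact zero contrast through a synthetic constant-Q pair
        zero = rule.contrast(np.zeros((1, 5)))
        d = np.where(zero >= 0, 1.0, -1.0)
        assert rule.decide(np.zeros((1, 5)))[0] == d[0]

    def test_decision_invariant_to_positive_rescaling(self, fixed_cohort,
                                                      fixed_qmodels):
        q_y, q_z = fixed_qmodels
        rule = TreatmentRule(FixedUtility(0.3), q_y, q_z)
        x = fixed_cohort.X[:100]
        d1 = rule.decide(x)
        d2 = np.where(10.0 * rule.contrast(x) >= 0, 1.0, -1.0)
        assert np.array_equal(d1, d2)

    def test_label_swap_equivariance_of_fitted_rule(self, fixed_cohort):
        """Refitting on the (Y<->Z)-swapped cohort with 1-omega gives the same rule."""
        q_y, q_z = fit_q(fixed_cohort, "y"), fit_q(fixed_cohort, "z")
        sw = fixed_cohort.swap_outcomes()
        q_y2, q_z2 = fit_q(sw, "y"), fit_q(sw, "z")
        x = fixed_cohort.X[:200]
        r1 = TreatmentRule(FixedUtility(0.25), q_y, q_z)
        r2 = TreatmentRule(FixedUtility(0.75), q_y2, q_z2)
        assert np.array_equal(r1.decide(x), r2.decide(x))

    def test_logistic_utility_gradient(self):
        u = LogisticUtility(np.array([1.0, -0.5, 0, 0, 0, 0]))
        x = np.random.default_rng(0).normal(size=(10, 5))
        eps = 1e-6
        for j in range(6):
            th = u.theta.copy()
            th[j] += eps
            num = (LogisticUtility(th).weight(x) - u.weight(x)) / eps
            np.testing.assert_allclose(u.gradient(x)[:, j], num, atol=1e-5)


class TestInfluenceBasis:
    def test_influence_means_are_zero(self, fixed_cohort, fixed_qmodels):
        q_y, q_z = fixed_qmodels
        rule = TreatmentRule(FixedUtility(0.25), q_y, q_z)
        basis = influence_basis(q_y, q_z, fixed_cohort, rule,
                                np.zeros(6))
        assert np.max(np.abs(basis.psi_y.mean(axis=0))) < 1e-8
        assert np.max(np.abs(basis.psi_z.mean(axis=0))) < 1e-8

    def test_beta_zero_psi_a_form(self, fixed_cohort, fixed_qmodels):
        q_y, q_z = fixed_qmodels
        rule = TreatmentRule(FixedUtility(0.25), q_y, q_z)
        basis = influence_basis(q_y, q_z, fixed_cohort, rule, np.zeros(6))
        conc = (fixed_cohort.A == rule.decide(fixed_cohort.X)).astype(float)
        expected = (conc - 0.5)[:, None] * add_intercept(fixed_cohort.X)
        np.testing.assert_allclose(basis.psi_a, expected, atol=1e-12)

    def test_influence_predicts_contrast_sampling_sd(self):
        """Monte-Carlo SD of sqrt(n) R_hat(x0) matches phi' Cov(psi) phi."""
        x0 = np.zeros((1, 5))
        rng = np.random.default_rng(99)
        n = 500
        vals, predicted = [], []
        for r in range(200):
            cfg = GenerativeConfig(n=n, utility=0.25, behavior=0.6,
                                   seed=int(rng.integers(2 ** 31)))
            c = simulate(cfg)
            q = fit_q(c, "y")
            vals.append(np.sqrt(n) * (q.contrast(x0)[0] - 4.0))
            if r < 50:
                psi = q.influence()
                phi = q.basis(x0)[0]
                predicted.append(np.sqrt(phi @ np.cov(psi.T) @ phi))
        mc_sd = np.std(vals, ddof=1)
        assert abs(mc_sd - np.mean(predicted)) / mc_sd < 0.15

    def test_unsupported_family_rejected(self, fixed_cohort, fixed_qmodels):
        from utilitr.qmodels import UnsupportedFamilyError
        q_y, q_z = fixed_qmodels
        rule = TreatmentRule(FixedUtility(0.25), q_y, q_z)
        with pytest.raises(UnsupportedFamilyError):
            influence_basis(object(), q_z, fixed_cohort, rule, np.zeros(6))
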