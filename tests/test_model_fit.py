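"""Fitting contracts: closed-form saturated oracle, constrained MLE,
parameterization equivalence and deviance identities."""

import numpy as np
import pytest
import statsmodels.api as sm

from addint.data import CountTable, DegenerateDataError, ZeroCellError
from addint.model_fit import (InfeasibleConstraintError, deviance,
                              fit_constrained, fit_unconstrained,
                              saturated_from_counts)
from conftest import random_tables


class TestUnconstrained:
    def test_oral_cancer_coefficients(self, oral_unconstrained):
        # the joint-exposure contrast equals the log cross-product ratio
        m = oral_unconstrained
        assert m.theta[2] == pytest.approx(np.log(225 * 20 / (166 * 3)),
                                           abs=1e-6)
        # single-factor contrasts (input column order: smoking, alcohol)
        assert sorted(np.round(m.theta[:2], 3)) == [1.086, 1.204]
        assert m.theta[2] == pytest.approx(2.201, abs=1e-3)
        assert m.gdev == pytest.approx(605.93, abs=0.02)
        assert m.df == 4 and not m.constrained and m.converged

    def test_uniform_table_has_null_coefficients(self):
        t = CountTable(cases=(10, 10, 10, 10), controls=(10, 10, 10, 10))
        m = saturated_from_counts(t)
        assert np.allclose(m.theta, 0.0)
        assert np.allclose(np.diag(m.covariance)[1:], 0.4)

    def test_saturated_agrees_with_optimizer(self):
        for table in random_tables(25, seed=42):
            closed = saturated_from_counts(table)
            iterative = fit_unconstrained(table)
            assert np.allclose(closed.theta, iterative.theta, atol=1e-6)
            assert closed.theta0 == pytest.approx(iterative.theta0, abs=1e-6)
            assert np.allclose(closed.covariance, iterative.covariance,
                               rtol=1e-4)
            assert closed.loglik == pytest.approx(iterative.loglik, abs=1e-6)

    def test_statsmodels_oracle(self, oral):
        """Independent check: GLM on the expanded individual data."""
        data = oral.to_dataset()
        X = data.design_matrix()
        fit = sm.Logit(data.outcome, X).fit(disp=0)
        ours = fit_unconstrained(oral)
        assert np.allclose(fit.params[1:], ours.theta, atol=1e-5)
        assert fit.llf == pytest.approx(ours.loglik, abs=1e-6)
        assert np.allclose(fit.cov_params()[1:, 1:], ours.theta_cov,
                           rtol=1e-4)

    def test_zero_cell_raises_with_cell_index(self):
        t = CountTable(cases=(3, 0, 6, 225), controls=(20, 18, 12, 166))
        with pytest.raises(ZeroCellError) as err:
            fit_unconstrained(t)
        assert (0, 1) in err.value.cells
        assert "a_only" in str(err.value)

    def test_all_same_outcome_degenerate(self):
        t = CountTable(cases=(5, 5, 5, 5), controls=(0, 0, 0, 0))
        with pytest.raises(DegenerateDataError):
            fit_unconstrained(t)

    def test_confounder_fit_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        n = 400
        level = rng.integers(0, 4, n)
        z = rng.normal(size=(n, 1))
        eta = -0.5 + 0.8 * (level == 1) + 0.6 * (level == 2) \
            + 1.2 * (level == 3) + 0.5 * z[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        from addint.data import ExposureDataset
        data = ExposureDataset(outcome=y, exposure_level=level,
                               confounders=z)
        ours = fit_unconstrained(data)
        ref = sm.Logit(y, data.design_matrix()).fit(disp=0)
        assert np.allclose(ours.params, ref.params, atol=1e-5)
        assert ours.df == 5


class TestConstrained:
    def test_oral_cancer_constrained(self, oral_constrained):
        m = oral_constrained
        assert sorted(np.round(m.theta[:2], 3)) == [1.497, 1.882]
        assert m.theta[2] == pytest.approx(2.306, abs=5e-3)
        assert m.gdev == pytest.approx(607.73, abs=0.02)
        assert abs(m.interaction_contrast) < 1e-8
        assert m.df == 3 and m.constrained and m.converged

    def test_loglik_never_exceeds_unconstrained(self):
        for table in random_tables(30, seed=3):
            m1 = fit_unconstrained(table)
            try:
                m2 = fit_constrained(table)
            except InfeasibleConstraintError:
                continue
            assert m2.loglik <= m1.loglik + 1e-9
            assert abs(m2.interaction_contrast) < 1e-8

    def test_exactly_additive_data_fits_both_models_equally(self):
        # expected counts of an exactly additive model: OR 4, 5, 8
        t = CountTable(cases=(500, 800, 833, 889),
                       controls=(500, 200, 167, 111))
        m1 = fit_unconstrained(t)
        m2 = fit_constrained(t)
        assert m2.loglik == pytest.approx(m1.loglik, abs=0.5)

    def test_infeasible_when_joint_cell_demands_zero_odds(self):
        # no cases among the jointly exposed and strongly protective
        # single exposures: the likelihood pushes e^t3 = e^t1 + e^t2 - 1
        # to 0, i.e. the boundary of the additive-null manifold
        t = CountTable(cases=(200, 2, 2, 0), controls=(100, 100, 100, 100))
        with pytest.raises(InfeasibleConstraintError):
            fit_constrained(t)

    def test_feasible_interior_optimum_for_protective_factors(self):
        # both factors protective but some joint-cell cases: the constrained
        # optimum is interior (small but positive joint odds ratio)
        t = CountTable(cases=(100, 5, 5, 4), controls=(100, 100, 100, 100))
        m = fit_constrained(t)
        assert m.converged
        assert abs(m.interaction_contrast) < 1e-8
        assert np.exp(m.theta[2]) < 0.1

    def test_lagrangian_limit_agrees_with_reparameterization(self, oral):
        from addint.regularized import penalized_fit
        m_lagrange = penalized_fit(oral, 1e6)
        m_exact = fit_constrained(oral)
        assert m_lagrange.loglik == pytest.approx(m_exact.loglik, abs=1e-4)

    def test_constraint_covariance_respects_manifold(self, oral_constrained):
        """Var(IC) at the constrained estimate must be ~0: the delta-method
        gradient of IC lies in the null space of the mapped covariance."""
        m = oral_constrained
        e1, e2, e3 = np.exp(m.theta)
        g = np.array([-e1, -e2, e3])
        var_ic = g @ m.theta_cov @ g
        assert abs(var_ic) < 1e-6


class TestDeviance:
    def test_training_deviance_identity(self, oral, oral_unconstrained,
                                        oral_constrained):
        assert deviance(oral_unconstrained, oral) == pytest.approx(
            -2 * oral_unconstrained.loglik, abs=1e-9)
        assert deviance(oral_constrained, oral) == pytest.approx(607.73,
                                                                 abs=0.02)
        gap = deviance(oral_constrained, oral) - deviance(oral_unconstrained,
                                                          oral)
        assert gap == pytest.approx(1.80, abs=0.02)

    def test_fair_coin_closed_form(self):
        # equal cases/controls per cell -> fitted p = 0.5, GDEV = 2n log 2
        t = CountTable(cases=(25, 25, 25, 25), controls=(25, 25, 25, 25))
        m = saturated_from_counts(t)
        assert m.gdev == pytest.approx(2 * t.n * np.log(2), abs=1e-9)

    def test_held_out_scoring(self, oral_unconstrained):
        other = CountTable(cases=(5, 10, 8, 200), controls=(25, 15, 10, 150))
        d = deviance(oral_unconstrained, other)
        assert d > 0
        assert d != pytest.approx(-2 * oral_unconstrained.loglik)

    def test_nesting_inequality_on_random_tables(self):
        for table in random_tables(30, seed=11):
            m1 = fit_unconstrained(table)
            try:
                m2 = fit_constrained(table)
            except InfeasibleConstraintError:
                continue
            assert m2.gdev - m1.gdev >= -1e-7


class TestParameterizationEquivalence:
    def test_product_term_model_matches_combined_levels(self):
        """A model with A, B and A*B gives b1 = t1, b2 = t2,
        b1 + b2 + b3 = t3 and the same maximized likelihood."""
        for table in random_tables(15, seed=29):
            data = table.to_dataset()
            a, b = data.factors()
            X = np.column_stack([np.ones(data.n), a, b, a * b])
            ref = sm.Logit(data.outcome, X).fit(disp=0)
            ours = fit_unconstrained(table)
            beta = ref.params
            assert beta[1] == pytest.approx(ours.theta[0], abs=1e-5)
            assert beta[2] == pytest.approx(ours.theta[1], abs=1e-5)
            assert beta[1] + beta[2] + beta[3] == pytest.approx(
                ours.theta[2], abs=1e-5)
            assert ref.llf == pytest.approx(ours.loglik, abs=1e-6)
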