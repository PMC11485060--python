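"""RERI/AP/S point estimators, their algebraic coherence, and the
delta-method intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addint.measures import (MeasureEstimate, ap, classify_interaction,
                             delta_ci, measure_gradient, reri, synergy_index)
from addint.model_fit import fit_unconstrained, saturated_from_counts

# printed two-decimal scenario algebra: (or10, or01, or11) -> (RERI, AP, S)
SCENARIO_ROWS = [
    ("S1", 4, 5, 20, 12.0, 0.60, 2.71),
    ("S2", 4, 5, 16, 8.0, 0.50, 2.14),
    ("S3", 4, 5, 12, 4.0, 0.33, 1.57),
    ("S4", 4, 5, 8, 0.0, 0.00, 1.00),
    ("S5", 4, 5, 6, -2.0, -0.33, 0.71),
    ("S6", 4, 5, 4, -4.0, -1.00, 0.43),
    ("S7", 4, 5, 2, -6.0, -3.00, 0.14),
]

finite_theta = st.tuples(
    st.floats(-2.0, 2.0), st.floats(-2.0, 2.0), st.floats(-2.0, 2.0))


class TestPointEstimators:
    @pytest.mark.parametrize("name,o10,o01,o11,r,a,s", SCENARIO_ROWS)
    def test_scenario_algebra(self, name, o10, o01, o11, r, a, s):
        theta = (math.log(o10), math.log(o01), math.log(o11))
        assert reri(theta) == pytest.approx(r, abs=5e-3)
        assert ap(theta) == pytest.approx(a, abs=5e-3)
        assert synergy_index(theta) == pytest.approx(s, abs=5e-3)

    def test_null_theta(self):
        assert reri((0, 0, 0)) == 0
        assert ap((0, 0, 0)) == 0
        # S is 0/0 at the exact null; additivity with effects gives S = 1
        assert synergy_index((math.log(2), math.log(2), math.log(3))) == \
            pytest.approx(1.0)

    def test_synergy_undefined_for_protective_pair(self):
        assert math.isnan(synergy_index((math.log(0.5), math.log(0.5), 1.0)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(theta=finite_theta)
    def test_ap_reri_identity(self, theta):
        assert ap(theta) * math.exp(theta[2]) == pytest.approx(
            reri(theta), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(theta=finite_theta)
    def test_sign_coherence(self, theta):
        tol = 1e-9
        r, a, s = reri(theta), ap(theta), synergy_index(theta)
        assert (abs(r) < tol) == (abs(a) < tol)
        if abs(r) >= tol:
            assert (r > 0) == (a > 0)
        if not math.isnan(s):
            # S - 1 shares the sign of RERI where S is defined
            if abs(r) < tol:
                assert s == pytest.approx(1.0, abs=1e-6)
            else:
                assert (r > 0) == (s > 1)

    def test_monotone_in_joint_effect(self):
        t1, t2 = math.log(2.0), math.log(3.0)
        grid = np.linspace(0.5, 3.0, 25)
        r = [reri((t1, t2, t3)) for t3 in grid]
        a = [ap((t1, t2, t3)) for t3 in grid]
        s = [synergy_index((t1, t2, t3)) for t3 in grid]
        assert np.all(np.diff(r) > 0)
        assert np.all(np.diff(a) > 0)
        assert np.all(np.diff(s) > 0)


class TestGradients:
    @pytest.mark.parametrize("measure", ["RERI", "AP", "S"])
    def test_against_finite_differences(self, measure):
        funcs = {"RERI": reri, "AP": ap,
                 "S": lambda t: math.log(synergy_index(t))}
        rng = np.random.default_rng(17)
        for _ in range(25):
            theta = rng.uniform(0.3, 1.8, size=3)
            theta[2] = theta.sum()          # keep S well-defined and > 0
            g = measure_gradient(measure, theta)
            h = 1e-6
            for k in range(3):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += h
                tm[k] -= h
                fd = (funcs[measure](tp) - funcs[measure](tm)) / (2 * h)
                assert g[k] == pytest.approx(fd, rel=1e-4)


class TestDeltaCI:
    def test_oral_cancer_all_verdicts_no_interaction(self, oral_unconstrained):
        for measure in ("RERI", "AP", "S"):
            est = delta_ci(oral_unconstrained, measure)
            assert est.verdict == "no_interaction"
            assert est.lower < est.point < est.upper

    def test_variance_matches_parametric_bootstrap(self):
        """Independent oracle: draw theta from the fitted normal and compare
        the empirical RERI variance with the delta-method variance on a
        well-populated table (small coefficient SEs, so the first-order
        Taylor approximation is accurate)."""
        from addint.data import CountTable
        t = CountTable(cases=(400, 600, 700, 1000),
                       controls=(800, 600, 500, 400))
        m = saturated_from_counts(t)
        rng = np.random.default_rng(5)
        draws = rng.multivariate_normal(m.theta, m.theta_cov, size=200_000)
        e = np.exp(draws)
        reri_draws = e[:, 2] - e[:, 0] - e[:, 1] + 1.0
        est = delta_ci(m, "RERI")
        z = 1.959963984540054
        delta_var = ((est.upper - est.lower) / (2 * z)) ** 2
        assert delta_var == pytest.approx(reri_draws.var(), rel=0.05)

    def test_constrained_model_rejected(self, oral_constrained):
        with pytest.raises(ValueError):
            delta_ci(oral_constrained, "RERI")

    def test_s_undefined_gives_undefined_verdict(self):
        # protective single factors: S denominator negative
        from addint.data import CountTable
        t = CountTable(cases=(100, 20, 20, 30), controls=(50, 50, 50, 50))
        est = delta_ci(fit_unconstrained(t), "S")
        assert est.verdict == "undefined"
        assert est.lower is None

    def test_interval_widens_with_level(self, oral_unconstrained):
        e90 = delta_ci(oral_unconstrained, "RERI", level=0.90)
        e99 = delta_ci(oral_unconstrained, "RERI", level=0.99)
        assert e99.upper - e99.lower > e90.upper - e90.lower

    def test_level_validated(self, oral_unconstrained):
        with pytest.raises(ValueError):
            delta_ci(oral_unconstrained, "RERI", level=1.2)


class TestClassification:
    @pytest.mark.parametrize("measure,lo,hi,null,expected", [
        ("RERI", -0.2, 3.1, 0.0, "no_interaction"),
        ("S", 1.2, 4.0, 1.0, "interaction"),
        ("AP", 0.0, 0.4, 0.0, "no_interaction"),   # boundary containment
        ("RERI", 0.5, 2.0, 0.0, "interaction"),
    ])
    def test_containment_rule(self, measure, lo, hi, null, expected):
        est = MeasureEstimate(measure=measure, point=(lo + hi) / 2, lower=lo,
                              upper=hi, null_value=null)
        assert classify_interaction(est) == expected

    def test_missing_bounds_undefined(self):
        est = MeasureEstimate(measure="S", point=float("nan"))
        assert classify_interaction(est) == "undefined"
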