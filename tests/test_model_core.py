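"""Model core: sigmoids, vector field, dynamic a-nullcline and its knees."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve, minimize_scalar

from rhythmcontrib import (DomainError, KneeSet, ModelParams, ParameterError,
                           State, find_knees, knee_condition_lhs, nullcline_s,
                           steady_state, vector_field)
from rhythmcontrib.model import KNEE_THRESHOLD, s_inf, theta_inf


class TestSteadyState:
    def test_midpoint_value(self):
        assert steady_state(0.3, center=0.3, spread=0.05) == pytest.approx(0.5)

    def test_closed_form_one_spread_above_center(self):
        # increasing sigmoid, center 0, spread 0.05, x = 0.05 -> 1/(1+e^-1)
        val = steady_state(0.05, center=0.0, spread=0.05, increasing=True)
        assert val == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(center=st.floats(-1, 1), delta=st.floats(-5, 5),
           spread=st.floats(0.01, 1.0))
    def test_symmetry_about_center(self, center, delta, spread):
        up = steady_state(center + delta, center, spread)
        dn = steady_state(center - delta, center, spread)
        assert up + dn == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(-0.4, 0.4), dx=st.floats(1e-3, 0.5))
    def test_strict_monotonicity_and_range(self, x, dx):
        lo = steady_state(x, 0.0, 0.05)
        hi = steady_state(x + dx, 0.0, 0.05)
        assert 0.0 < lo < hi < 1.0
        assert steady_state(x, 0.0, 0.05, increasing=False) > steady_state(
            x + dx, 0.0, 0.05, increasing=False)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ParameterError):
            steady_state(0.1, 0.0, 0.0)


class TestVectorField:
    def test_slow_variables_at_steady_state_have_zero_rate(self, default_params):
        p = default_params
        a = 0.42
        state = State(a=a, s=s_inf(a, p), theta=theta_inf(a, p))
        _, ds, dtheta = vector_field(state, p)
        assert ds == pytest.approx(0.0, abs=1e-15)
        assert dtheta == pytest.approx(0.0, abs=1e-15)

    def test_full_fixed_point_found_by_root_solver(self):
        # quiescent regime (high threshold): a stable low-activity rest
        # state exists and all three rates vanish there
        p = ModelParams(theta0=0.3)

        def f(y):
            return vector_field(State(a=y[0], s=y[1], theta=y[2]), p)

        root = fsolve(f, [0.01, 1.0, 0.01], full_output=False, xtol=1e-14)
        res = np.abs(f(root)).max()
        assert res < 1e-12
        assert np.all((root > 0) & (root < 1))

    def test_g_zero_decouples_theta_from_activity(self, default_params):
        p = default_params.replace(g=0.0)
        da1 = vector_field(State(0.4, 0.8, 0.1), p)[0]
        da2 = vector_field(State(0.4, 0.8, 0.9), p)[0]
        assert da1 == da2


class TestNullcline:
    def test_log_term_vanishes_at_half_activity(self, default_params):
        p = default_params
        theta = 0.2
        expected = (p.g * theta + p.theta0) / (0.5 * p.w)
        assert nullcline_s(0.5, theta, p) == pytest.approx(expected, abs=1e-14)

    def test_point_on_nullcline_has_zero_activity_rate(self, default_params):
        p = default_params
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.uniform(0.01, 0.99)
            theta = rng.uniform(0.0, 1.0)
            s = nullcline_s(a, theta, p)
            da = vector_field(State(a=a, s=s, theta=theta), p)[0]
            assert abs(da) < 1e-10

    def test_domain_error_at_boundaries(self, default_params):
        with pytest.raises(DomainError):
            nullcline_s(0.0, 0.1, default_params)
        with pytest.raises(DomainError):
            nullcline_s(1.0, 0.1, default_params)

    def test_s_shape_has_two_stationary_points(self, default_params):
        # dense scan of ds/da sign changes at theta = 0.2
        p = default_params
        a = np.linspace(1e-4, 1 - 1e-4, 200_001)
        s = nullcline_s(a, 0.2, p)
        signs = np.sign(np.diff(s))
        flips = np.nonzero(np.diff(signs) != 0)[0]
        assert len(flips) == 2


class TestKnees:
    def test_minimum_of_knee_condition_is_two_at_one_half(self):
        res = minimize_scalar(knee_condition_lhs, bounds=(1e-6, 1 - 1e-6),
                              method="bounded",
                              options={"xatol": 1e-12})
        assert res.x == pytest.approx(0.5, abs=1e-6)
        assert res.fun == pytest.approx(KNEE_THRESHOLD, abs=1e-10)

    def test_no_knees_when_condition_not_exceeded(self, default_params):
        # rhs = (g*theta + theta0)/k_a = 0.05/0.05 = 1 < 2
        ks = find_knees(theta=0.05, p=default_params)
        assert ks == KneeSet(theta=0.05, exists=False)

    def test_borderline_double_root_reports_nonexistence(self, default_params):
        # rhs exactly 2: theta = 2*k_a/g
        theta = 2.0 * default_params.k_a / default_params.g
        assert not find_knees(theta, default_params).exists

    def test_default_theta_yields_two_knees_with_small_residual(
            self, default_params):
        p = default_params
        ks = find_knees(theta=0.3, p=p)
        assert ks.exists
        assert ks.a_LK < 0.5 < ks.a_HK
        rhs = (p.g * 0.3 + p.theta0) / p.k_a
        for a_k in (ks.a_LK, ks.a_HK):
            assert abs(knee_condition_lhs(a_k) - rhs) < 1e-9
        # dense-grid oracle: independent location of the sign changes
        a = np.linspace(1e-6, 1 - 1e-6, 2_000_001)
        f = knee_condition_lhs(a) - rhs
        flips = np.nonzero(np.sign(f[:-1]) != np.sign(f[1:]))[0]
        assert len(flips) == 2
        assert abs(a[flips[0]] - ks.a_LK) < 1e-5
        assert abs(a[flips[1]] - ks.a_HK) < 1e-5

    def test_knee_s_coordinates_lie_on_nullcline(self, default_params):
        ks = find_knees(theta=0.3, p=default_params)
        assert ks.s_LK == pytest.approx(
            nullcline_s(ks.a_LK, 0.3, default_params))
        assert ks.s_HK == pytest.approx(
            nullcline_s(ks.a_HK, 0.3, default_params))

    def test_existence_flips_exactly_at_threshold(self, default_params):
        # scan rhs = theta0/k_a (g*theta = 0) across [1.5, 3] by bisection
        p = default_params

        def exists(rhs):
            return find_knees(0.0, p.replace(theta0=rhs * p.k_a)).exists

        assert not exists(1.5)
        assert exists(3.0)
        lo, hi = 1.5, 3.0
        while hi - lo > 1e-8:
            mid = 0.5 * (lo + hi)
            if exists(mid):
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(KNEE_THRESHOLD, abs=1e-6)


class TestModelParams:
    def test_invalid_parameters_rejected(self):
        for bad in (dict(tau_s=0), dict(k_a=-1), dict(g=-0.1), dict(dt=0),
                    dict(dt=50.0)):
            with pytest.raises(ParameterError):
                ModelParams(**bad)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ParameterError):
            ModelParams.from_mapping({"tau_x": 1.0})

    def test_roundtrip_through_mapping(self, default_params):
        assert ModelParams.from_mapping(
            default_params.to_dict()) == default_params
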