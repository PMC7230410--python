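"""Closed-form solution of the glucose response ODE: regimes, values, derivatives."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glycofit.model import (
    ModelParameters,
    Regime,
    classify_regime,
    derivative,
    evaluate,
    period,
)
from tests.conftest import random_params


def integrate_ode(params, t_eval):
    """Independent oracle: 4th/5th-order numerical integration of
    g'' + 2*alpha*g' + omega0_sq*g = 0 from the same initial data."""
    a, w2 = params.alpha, params.omega0_sq

    def rhs(t, y):
        return [y[1], -2 * a * y[1] - w2 * y[0]]

    sol = solve_ivp(
        rhs,
        (0, t_eval[-1]),
        [params.mu - params.g_stab, params.nu],
        t_eval=t_eval,
        rtol=1e-11,
        atol=1e-12,
        method="DOP853",
    )
    return params.g_stab + sol.y[0]


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "alpha,w2,regime,roots",
        [
            (0.10, 0.0019, Regime.OVERDAMPED, (-0.01, -0.19)),
            (0.02, 0.0008, Regime.UNDERDAMPED, None),
            (0.05, 0.0025, Regime.CRITICAL, None),
        ],
    )
    def test_regime_examples(self, alpha, w2, regime, roots):
        info = classify_regime(ModelParameters(alpha, w2, 5.0, 5.0, 0.0))
        assert info.regime is regime
        if roots is not None:
            assert info.r1 == pytest.approx(roots[0], abs=1e-12)
            assert info.r2 == pytest.approx(roots[1], abs=1e-12)
        if regime is Regime.UNDERDAMPED:
            assert info.omega == pytest.approx(math.sqrt(w2 - alpha**2))

    def test_overdamped_root_identities(self, rng):
        for p in random_params(rng, 30):
            info = classify_regime(p)
            if info.regime is Regime.OVERDAMPED:
                assert info.r1 < 0 and info.r2 < 0 and info.r1 != info.r2
                assert info.r1 * info.r2 == pytest.approx(p.omega0_sq, rel=1e-9)
                assert info.r1 + info.r2 == pytest.approx(-2 * p.alpha, rel=1e-9)
            elif info.regime is Regime.UNDERDAMPED:
                assert info.omega > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(float("nan"), 0.001, 5, 5, 0)
        with pytest.raises(ValueError):
            ModelParameters(-0.1, 0.001, 5, 5, 0)
        with pytest.raises(ValueError):
            ModelParameters(0.1, -0.001, 5, 5, 0)
        with pytest.raises(ValueError):
            ModelParameters(0.1, 0.001, 5, -5, 0)


class TestEvaluate:
    def test_equilibrium_initial_data_gives_constant(self):
        p = ModelParameters(0.07, 0.003, 6.2, 6.2, 0.0)
        t = np.linspace(0, 240, 50)
        assert np.allclose(evaluate(p, t), 6.2, atol=1e-14)

    def test_initial_condition_exact(self, rng):
        for p in random_params(rng, 20):
            assert evaluate(p, 0.0) == p.mu

    def test_against_ode_integrator_example(self):
        p = ModelParameters(0.02, 0.0008, 5.0, 5.5, 0.4)
        t = np.linspace(0, 240, 241)
        ref = integrate_ode(p, t)
        assert np.max(np.abs(np.asarray(evaluate(p, t)) - ref)) < 1e-6

    def test_negative_time_rejected(self):
        p = ModelParameters(0.02, 0.0008, 5.0, 5.5, 0.4)
        with pytest.raises(ValueError):
            evaluate(p, -1.0)

    def test_ode_residual_property(self, rng):
        """The analytic solution satisfies its own ODE to 1e-8 relative."""
        for p in random_params(rng, 20):
            t = rng.uniform(0, 240, size=100)
            g = np.asarray(evaluate(p, t)) - p.g_stab
            g1 = np.asarray(derivative(p, t, 1))
            g2 = np.asarray(derivative(p, t, 2))
            resid = g2 + 2 * p.alpha * g1 + p.omega0_sq * g
            scale = max(np.max(np.abs(g)), 1e-12)
            assert np.max(np.abs(resid)) < 1e-8 * scale

    def test_continuity_across_critical_boundary(self):
        """Evaluate is continuous in omega0_sq through alpha^2."""
        t = np.linspace(0, 240, 481)
        for alpha in (0.02, 0.08):
            lo = ModelParameters(alpha, alpha**2 * (1 - 1e-6), 5.5, 7.0, 0.3)
            hi = ModelParameters(alpha, alpha**2 * (1 + 1e-6), 5.5, 7.0, 0.3)
            assert classify_regime(lo).regime is Regime.OVERDAMPED
            assert classify_regime(hi).regime is Regime.UNDERDAMPED
            d = np.abs(np.asarray(evaluate(lo, t)) - np.asarray(evaluate(hi, t)))
            assert np.max(d) < 1e-4

    def test_critical_regime_evaluates_finite(self):
        p = ModelParameters(0.05, 0.0025, 5.0, 7.0, -0.2)
        t = np.linspace(0, 240, 100)
        y = np.asarray(evaluate(p, t))
        assert np.all(np.isfinite(y))
        ref = integrate_ode(p, t)
        assert np.max(np.abs(y - ref)) < 1e-6


class TestDerivative:
    def test_initial_rate_is_nu(self, rng):
        for p in random_params(rng, 10):
            assert derivative(p, 0.0, 1) == pytest.approx(p.nu, abs=1e-14)

    def test_constant_solution_has_zero_derivatives(self):
        p = ModelParameters(0.03, 0.001, 5.0, 5.0, 0.0)
        for order in (1, 2):
            assert derivative(p, 37.0, order) == 0.0

    def test_finite_difference_oracle(self, rng):
        h = 1e-4
        p0 = ModelParameters(0.02, 0.0008, 5.0, 5.5, 0.4)
        fd = (evaluate(p0, 20 + h) - evaluate(p0, 20 - h)) / (2 * h)
        assert abs(derivative(p0, 20.0, 1) - fd) < 1e-5
        for p in random_params(rng, 10):
            t = float(rng.uniform(1, 200))
            fd1 = (evaluate(p, t + h) - evaluate(p, t - h)) / (2 * h)
            fd2 = (evaluate(p, t + h) - 2 * evaluate(p, t) + evaluate(p, t - h)) / h**2
            assert abs(derivative(p, t, 1) - fd1) < 1e-5
            assert abs(derivative(p, t, 2) - fd2) < 1e-4

    def test_invalid_order(self):
        p = ModelParameters(0.02, 0.0008, 5.0, 5.5, 0.4)
        with pytest.raises(ValueError):
            derivative(p, 1.0, 3)


class TestPeriod:
    def test_pure_oscillator_four_hours(self):
        w = 2 * math.pi / 240.0
        p = ModelParameters(0.0, w**2, 5.0, 5.0, 0.1)
        assert period(p) == pytest.approx(4.0)

    def test_overdamped_has_no_period(self):
        p = ModelParameters(0.10, 0.0019, 5.0, 5.5, 0.2)
        assert period(p) is None

    def test_damped_example(self):
        p = ModelParameters(0.02, 0.0008, 5.0, 5.5, 0.4)
        # omega = sqrt(0.0008 - 0.0004) = 0.02 -> 2*pi/0.02 min = 5.236 h
        assert period(p) == pytest.approx(2 * math.pi / 0.02 / 60.0, rel=1e-12)
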