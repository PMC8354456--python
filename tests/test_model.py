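"""Potential functions, steady states, and slowdown schedule."""

import math

import numpy as np
import pytest

from l1agg.model import (ModelParameters, SlowdownSchedule,
                         crowding_potential, crowding_potential_derivative,
                         effective_motility, signal_potential,
                         signal_potential_derivative, signal_range,
                         slowdown_factor, total_potential,
                         uniform_steady_state)

P = ModelParameters()


class TestSignalPotential:
    def test_boundary_value_at_zero(self):
        assert signal_potential(0.0, 1500.0, 2e-5) == pytest.approx(
            -2e-5 * math.log(1500.0))

    def test_hand_derived_value(self):
        # U = alpha*(e-1) makes log(alpha+U) = 1 + log(alpha)
        alpha, beta = 1500.0, 1.111e-5
        U = alpha * (math.e - 1.0)
        assert signal_potential(U, alpha, beta) == pytest.approx(
            -beta * (1.0 + math.log(alpha)), rel=1e-12)

    @pytest.mark.parametrize("beta,sign", [(1.111e-5, -1), (-1.111e-5, +1)])
    def test_monotonicity_follows_beta_sign(self, beta, sign):
        U = np.linspace(0.0, 5e4, 200)
        dV = np.diff(signal_potential(U, 1500.0, beta))
        assert np.all(sign * dV > 0)

    def test_derivative_direct_substitution(self):
        sigma = P.sigma
        assert signal_potential_derivative(0.0, 1500.0, 2 * sigma) == \
            pytest.approx(-2 * sigma / 1500.0)

    def test_attractant_repellent_antisymmetry(self):
        # beta_r = -beta_a, alpha_r = alpha_a: derivatives cancel at equal U
        U = 9000.0
        total = (signal_potential_derivative(U, P.alpha_a, P.beta_a)
                 + signal_potential_derivative(U, P.alpha_r, P.beta_r))
        assert total == pytest.approx(0.0, abs=1e-25)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            signal_potential(-1.0, 1500.0, 1e-5)
        with pytest.raises(ValueError):
            signal_potential(1.0, 0.0, 1e-5)


class TestCrowdingPotential:
    def test_midpoint_value(self):
        # tanh(0) = 0 -> half height = sigma*scale/2
        assert crowding_potential(P.rho_max, P) == pytest.approx(
            P.sigma * P.scale / 2.0, rel=1e-12)
        assert crowding_potential(P.rho_max, P) == pytest.approx(5.555e-6)

    def test_negligible_at_zero_density(self):
        assert crowding_potential(0.0, P) < 1e-17

    def test_bounded_by_sigma_scale(self):
        rho = np.linspace(0.0, 3e5, 500)
        V = crowding_potential(rho, P)
        assert np.all(np.diff(V) >= 0)
        assert np.all(V <= P.sigma * P.scale)   # tanh saturates to 1 in float
        assert crowding_potential(3e6, P) == pytest.approx(
            P.sigma * P.scale, rel=1e-9)

    def test_derivative_peak_at_rho_max(self):
        rho = np.linspace(0.0, 1e5, 2001)
        d = crowding_potential_derivative(rho, P)
        assert np.all(d > 0)
        assert rho[np.argmax(d)] == pytest.approx(P.rho_max, abs=100)
        assert d.max() == pytest.approx(P.sigma * P.scale / (2 * P.cushion),
                                        rel=1e-4)

    def test_negligible_at_threshold_density(self):
        # sech^2(-13.25)*sigma*scale/(2*cushion) ~ 3.4e-20, fourteen orders
        # below sigma: the crowding term cannot move the thresholds
        assert crowding_potential_derivative(1500.0, P) < 1e-19


@pytest.mark.parametrize("func,dfunc,args,x", [
    (signal_potential, signal_potential_derivative, (1500.0, 1.111e-5), 5000.0),
    (crowding_potential, crowding_potential_derivative, (P,), 27000.0),
])
def test_derivatives_match_central_differences(func, dfunc, args, x):
    h = x * 1e-6
    fd = (func(x + h, *args) - func(x - h, *args)) / (2 * h)
    assert dfunc(x, *args) == pytest.approx(fd, rel=1e-6)


def test_derivatives_match_central_differences_log_grid():
    for x in np.logspace(1, 5, 9):
        h = max(x, 1.0) * 1e-6
        fd = (signal_potential(x + h, 1500.0, 1e-5)
              - signal_potential(x - h, 1500.0, 1e-5)) / (2 * h)
        assert signal_potential_derivative(x, 1500.0, 1e-5) == \
            pytest.approx(fd, rel=1e-6)
        fd = (crowding_potential(x + h, P) - crowding_potential(x - h, P)) / (2 * h)
        d = crowding_potential_derivative(x, P)
        if abs(d) > 1e-30:          # below that, cancellation dominates
            assert d == pytest.approx(fd, rel=1e-5)


class TestTotalPotential:
    def test_equal_concentrations_cancel(self):
        # beta_r = -beta_a: at U_a = U_r the signal terms cancel exactly
        V = total_potential(9000.0, 9000.0, 9000.0, P)
        assert V == pytest.approx(float(crowding_potential(9000.0, P)), rel=1e-9)

    def test_antisymmetric_cancellation_over_grid(self):
        U = np.logspace(0, 5, 50)
        V = (signal_potential(U, P.alpha_a, P.beta_a)
             + signal_potential(U, P.alpha_r, P.beta_r))
        assert np.ptp(V) < 1e-20

    def test_attractant_only_additivity(self):
        pa = P.attractant_only()
        rho, U = 12000.0, 7000.0
        assert total_potential(rho, U, None, pa) == pytest.approx(
            float(signal_potential(U, pa.alpha_a, pa.beta_a))
            + float(crowding_potential(rho, pa)))

    def test_uniform_fields_give_constant(self):
        rho = np.full((8, 8), 5000.0)
        V = total_potential(rho, rho, rho, P)
        assert np.ptp(V) == 0.0


class TestSteadyStateAndRange:
    def test_concentrations_equal_density_numerically(self):
        assert uniform_steady_state(9000.0, P) == (9000.0, 9000.0)
        assert uniform_steady_state(0.0, P) == (0.0, 0.0)
        assert uniform_steady_state(2357.0, P) == (2357.0, 2357.0)

    def test_attractant_and_repellent_ranges(self):
        assert signal_range(1e-6, 0.01) == pytest.approx(0.01)    # 100 um
        assert signal_range(1e-5, 0.001) == pytest.approx(0.1)    # 1 mm
        assert signal_range(3.3e-4, 3.3e-4) == pytest.approx(1.0)

    def test_range_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            signal_range(-1e-6, 0.01)


class TestSlowdown:
    def test_factor_values(self):
        sch = SlowdownSchedule(tau=1800.0, enabled=True)
        assert slowdown_factor(0.0, sch) == 1.0
        assert slowdown_factor(1800.0, sch) == pytest.approx(math.exp(-1))
        assert slowdown_factor(1e9, SlowdownSchedule(enabled=False)) == 1.0
        with pytest.raises(ValueError):
            slowdown_factor(-1.0, sch)

    def test_effective_motility_scales_worm_parameters_only(self):
        sch = SlowdownSchedule(tau=3600.0, enabled=True)
        sigma, ba, br = effective_motility(P, sch, 3600.0)
        f = math.exp(-1)
        assert sigma == pytest.approx(P.sigma * f)
        assert ba == pytest.approx(P.beta_a * f)
        assert br == pytest.approx(P.beta_r * f)


class TestParameterInvariants:
    def test_defaults_match_reference_values(self):
        assert P.sigma == 5.555e-6
        assert P.beta_a == 1.111e-5
        assert P.beta_r == -1.111e-5
        assert (P.rho_max, P.cushion, P.scale) == (28000.0, 2000.0, 2.0)
        assert (P.gamma_a, P.D_a, P.s_a) == (0.01, 1e-6, 0.01)
        assert (P.gamma_r, P.D_r, P.s_r) == (0.001, 1e-5, 0.001)
        assert P.alpha_a == P.alpha_r == 1500.0

    @pytest.mark.parametrize("bad", [
        {"sigma": -1e-6}, {"gamma_a": 0.0}, {"D_r": -1.0}, {"cushion": 0.0},
        {"dim": 3},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)
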