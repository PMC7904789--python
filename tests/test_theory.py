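"""Kramers two-state theory: closed forms, limits, and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexcat import stimuli, theory
from flexcat.models import IntegratorConfig, simulate
from flexcat.potentials import SingleWellError, double_well


class TestFixedStructure:
    def test_symmetric_well_positions(self):
        x_e, x_u, x_c = theory.fixed_points(double_well(0.0, 0.5))
        np.testing.assert_allclose([x_e, x_u, x_c], [-0.5, 0.0, 0.5], atol=1e-12)

    @pytest.mark.parametrize("alpha, expected", [(0.5, 0.125), (2.0, 1.0)])
    def test_critical_tilt_closed_form(self, alpha, expected):
        assert theory.critical_mu(alpha) == pytest.approx(expected)

    def test_no_barrier_for_nonpositive_alpha(self):
        with pytest.raises(SingleWellError):
            theory.critical_mu(-1.0)


class TestFirstVisit:
    def test_symmetric_case_is_half(self):
        assert theory.first_visit_probability(double_well(0.0, 1.0), 0.3) == pytest.approx(0.5)

    def test_weak_noise_limit_is_certainty(self):
        p0 = theory.first_visit_probability(double_well(0.15, 1.0), 1e-3)
        assert p0 == pytest.approx(1.0, abs=1e-12)

    def test_erf_form_tracks_exact_quadrature_at_low_noise(self):
        pot = double_well(0.1, 1.0)
        for sigma in (0.15, 0.2, 0.25):
            erf_p = theory.first_visit_probability(pot, sigma)
            quad_p = theory.first_visit_probability(pot, sigma, method="quadrature")
            assert abs(erf_p - quad_p) < 0.01


class TestRates:
    def test_hand_evaluated_symmetric_rate(self):
        # curvature prefactor sqrt(2.8 * 1.4)/(2 pi), barrier alpha^2/4
        k_c, k_e = theory.transition_rates(double_well(0.0, 0.70), 0.32)
        expected = np.sqrt(2.8 * 1.4) / (2 * np.pi) * np.exp(-2 * 0.1225 / 0.32**2)
        assert k_c == pytest.approx(expected, rel=1e-12)
        assert k_c == pytest.approx(k_e)
        assert k_c == pytest.approx(0.0288, abs=5e-4)

    def test_rate_ratio_small_tilt_exponential(self):
        # k_C/k_E ~ exp(4 mu sqrt(alpha/2)/sigma^2) for small mu; the exact
        # fixed points add O(mu^2) barrier terms, so the relative error grows
        # with mu (about 1% at mu = 0.02, 5% at mu = 0.05)
        for mu, tol in ((0.01, 0.015), (0.02, 0.03), (0.05, 0.07)):
            k_c, k_e = theory.transition_rates(double_well(mu, 1.0), 0.4)
            expected = np.exp(4 * mu * np.sqrt(0.5) / 0.4**2)
            assert abs(k_c / k_e - expected) / expected < tol

    def test_per_second_conversion(self):
        k_c, _ = theory.transition_rates(double_well(0.0, 1.0), 0.4)
        k_c_s, _ = theory.rates_per_second(double_well(0.0, 1.0), 0.4, tau=0.2)
        assert k_c_s == pytest.approx(k_c / 0.2)


class TestTrialProbabilities:
    def test_zero_duration_no_transitions(self):
        p_c, p_e, _ = theory.trial_transition_probs(0.3, 0.1, 0.0)
        assert p_c == 0.0 and p_e == 0.0

    def test_infinite_duration_saturates_at_stationary_split(self):
        p_c, p_e, p_inf = theory.trial_transition_probs(0.3, 0.1, 1e9)
        assert p_c == pytest.approx(p_inf)
        assert p_e == pytest.approx(1 - p_inf)
        assert p_inf == pytest.approx(0.75)

    def test_correcting_exceeds_error_for_positive_tilt(self):
        k_c, k_e = theory.transition_rates(double_well(0.1, 1.0), 0.4)
        p_c, p_e, _ = theory.trial_transition_probs(k_c, k_e, 5.0)
        assert p_c > p_e

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 0.2), st.floats(0.5, 2.0), st.floats(0.15, 0.6),
        st.floats(0.0, 20.0),
    )
    def test_chain_and_relaxation_forms_agree(self, mu, alpha, sigma, T):
        """P0(1-pE)+(1-P0)pC == P0 e^{-kT} + Pinf(1-e^{-kT}) to 1e-12."""
        if mu >= theory.critical_mu(alpha):
            return
        # predict() raises if the two algebraic forms of P disagree
        pred = theory.predict(double_well(mu, alpha), sigma, T)
        assert 0.0 <= pred.accuracy <= 1.0
        assert pred.p_c >= pred.p_e - 1e-12


class TestAccuracyShape:
    def test_symmetric_case_stays_at_chance(self):
        for sigma in (0.2, 0.5, 1.0):
            for T in (1.0, 10.0):
                assert theory.accuracy(double_well(0.0, 1.0), sigma, T) == pytest.approx(0.5)

    def test_interior_maximum_below_critical_tilt(self):
        res = theory.accuracy_local_maximum(alpha=1.0, mu=0.15, T_over_tau=10.0)
        assert res["interior"]
        assert res["p_max"] > res["p_min"] + 0.01  # genuine bump
        assert res["sigma_max"] > res["sigma_min"]

    def test_maximum_disappears_above_critical_tilt(self):
        # beyond mu_C the exact double well ceases to exist; the perturbative
        # continuation shows monotone decay (no interior bump)
        mu_c = theory.critical_mu(1.0)
        res = theory.accuracy_local_maximum(
            alpha=1.0, mu=1.2 * mu_c, T_over_tau=10.0,
            sigma_grid=np.geomspace(0.12, 2.0, 150), fp_method="perturbative",
        )
        assert not res["interior"]
        values = res["grid_values"]
        assert np.all(np.diff(values) <= 1e-9)  # monotone decay

    def test_closed_form_maximum_location_mode(self):
        s = theory.closed_form_sigma_max(alpha=1.0, T_over_tau=10.0, z0=1.0)
        assert 0.1 < s < 1.5
        with pytest.raises(ValueError):
            theory.closed_form_sigma_max(alpha=0.1, T_over_tau=0.1, z0=10.0)


class TestDelaySwitches:
    def test_vanishing_internal_noise_cannot_switch(self):
        assert theory.delay_switch_probability(0.7, 0.0, 3.3, 1.08) == 0.0

    def test_fitted_parameters_give_sub_percent_switches(self):
        p = theory.delay_switch_probability(0.70, 0.32, 3.3, 1.08)
        assert p == pytest.approx(0.0093, abs=3e-4)
        assert p < 0.01

    def test_noise_bound_reproduces_printed_value(self):
        s = theory.max_internal_noise(0.70, 3.3, 1.08, threshold=0.01)
        assert round(s, 2) == 0.32

    def test_bound_monotone_in_barrier_and_clock(self):
        base = theory.max_internal_noise(0.70, 3.3, 1.08)
        assert theory.max_internal_noise(0.90, 3.3, 1.08) > base
        assert theory.max_internal_noise(0.70, 5.0, 1.08) > base


class TestSimulationOracles:
    def test_equilibrium_switch_rate_matches_kramers(self):
        """Mean attractor-switch rate in equilibrium vs Eqs. of the rate theory.

        Trials start inside an attractor so no settling transient biases the
        count; the residual Kramers error at barrier ~ 2.8 sigma^2 is a few
        percent.
        """
        pot = double_well(0.0, 1.0)
        sigma, T_over_tau, n = 0.30, 60.0, 1200
        k_th, _ = theory.transition_rates(pot, sigma)
        st_ = stimuli.gaussian_frames(n, int(T_over_tau * 40), 0.0, sigma, seed=16)
        ens = simulate(st_, pot, None,
                       IntegratorConfig(seed=16, x0=float(np.sqrt(0.5))))
        count = ens.n_transitions.sum()
        rate_emp = count / (n * T_over_tau)
        se = np.sqrt(count) / (n * T_over_tau)  # Poisson-like counting error
        assert abs(rate_emp - k_th) < 0.15 * k_th + 2 * se

    def test_accuracy_matches_monte_carlo_in_validity_region(self):
        n = 4000
        for mu, alpha, sigma in ((0.05, 1.0, 0.25), (0.15, 1.0, 0.22)):
            pot = double_well(mu, alpha)
            th = theory.accuracy(pot, sigma, 2.5, p0_method="quadrature")
            st_ = stimuli.gaussian_frames(n, 100, mu, sigma, seed=15)
            ens = simulate(st_, pot, None, IntegratorConfig(seed=15))
            mc = ens.accuracy()
            se = np.sqrt(mc * (1 - mc) / n)
            assert abs(th - mc) < 2 * se
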