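"""Two-pulse working-memory analysis: closed forms, fit, PRI, delay bound."""

import numpy as np
import pandas as pd
import pytest

from flexcat import pulsefit
from flexcat.pulsefit import (
    PulseParams,
    delay_robustness,
    fit,
    log_likelihood,
    model_pri,
    pool_delays,
    predict_double,
    predict_single,
    pri,
    simulate_condition_table,
    simulate_trials,
)


class TestClosedForms:
    def test_zero_coherence_is_chance(self, fitted_params):
        assert predict_single(0.0, fitted_params) == 0.5
        assert predict_double(0.0, 0.0, fitted_params) == 0.5

    def test_strong_pulse_weak_noise_is_certain(self, fitted_params):
        params = PulseParams(k=0.012, alpha=0.70, sigma=0.06, tau_s=3.3)
        assert predict_single(51.2, params) > 0.99

    def test_accuracy_increases_with_coherence(self, fitted_params):
        cohs = [0.0, 3.2, 6.4, 12.8, 25.6, 51.2]
        p = predict_single(cohs, fitted_params)
        assert np.all(np.diff(p) > 0)

    def test_two_congruent_pulses_beat_one(self, fitted_params):
        for c in (3.2, 6.4, 12.8):
            assert predict_double(c, c, fitted_params) >= predict_single(c, fitted_params)

    def test_second_pulse_chains_through_transition_probs(self, fitted_params):
        """A zero-rate second pulse leaves the first-pulse accuracy intact."""
        p1 = predict_single(6.4, fitted_params)
        assert pulsefit._pulse_step(p1, 0.0, fitted_params) != p1  # rates act at coh 0 too
        frozen = PulseParams(k=0.012, alpha=0.70, sigma=1e-6, tau_s=3.3)
        assert pulsefit._pulse_step(0.77, 0.0, frozen) == pytest.approx(0.77, abs=1e-9)

    def test_saturating_noise_limit_approaches_chance_symmetrically(self):
        # at very large sigma the erf arguments linearize and P0 tends to the
        # positional split (x0 - x_E)/(x_C - x_E), a hair below 1/2 for a
        # tilted well; both pulse orders share that limit
        params = PulseParams(k=0.012, alpha=0.70, sigma=50.0, tau_s=3.3)
        a = predict_double(12.8, 3.2, params)
        b = predict_double(3.2, 12.8, params)
        assert a == pytest.approx(0.5, abs=0.06)
        assert a == pytest.approx(b, abs=0.05)

    def test_monte_carlo_oracle_single_pulse(self):
        """Closed-form single-pulse accuracy vs direct SDE simulation.

        The closed form assumes instantaneous categorization, which holds
        when tau is short relative to the pulse; parameters are chosen inside
        the Kramers validity region for the oracle comparison.
        """
        from flexcat import stimuli
        from flexcat.models import IntegratorConfig, simulate
        from flexcat.potentials import double_well

        params = PulseParams(k=0.012, alpha=1.0, sigma=0.25, tau_s=0.012)
        coh = 12.8
        closed = predict_single(coh, params)
        n = 8000
        dt = params.tau_s / 40
        n_frames = int(round(0.120 / dt))
        st = stimuli.gaussian_frames(n, n_frames, params.k * coh, params.sigma,
                                     seed=17, frame_duration=dt)
        ens = simulate(st, double_well(params.k * coh, 1.0), None,
                       IntegratorConfig(tau=params.tau_s, seed=17))
        mc = ens.accuracy()
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(closed - mc) < 3 * se


class TestFit:
    def test_pool_delays_merges_replicates(self, fitted_params):
        tab = simulate_condition_table(fitted_params, 500, seed=1,
                                       do_pool_delays=False)
        pooled = pool_delays(tab)
        assert len(pooled) == 6 + 9
        assert pooled["n_trials"].sum() == tab["n_trials"].sum()

    def test_likelihood_printed_form_behind_flag(self, fitted_params):
        tab = simulate_condition_table(fitted_params, 500, seed=2)
        ll = log_likelihood(tab, fitted_params)
        printed = log_likelihood(tab, fitted_params, printed_form=True)
        assert ll < 0 < printed  # the printed form is not a log-likelihood

    def test_recovery_within_own_confidence_intervals(self, fitted_params):
        tab = simulate_condition_table(fitted_params, 10_000, seed=3)
        res = fit(tab, seed=3, n_restarts=6)
        assert res.loglik >= log_likelihood(tab, fitted_params) - 1e-6
        for name in pulsefit.PARAM_NAMES:
            err = abs(getattr(res.params, name) - getattr(fitted_params, name))
            assert err <= res.ci95[name]
        assert np.all((res.predictions["p_model"] > 0) & (res.predictions["p_model"] < 1))

    def test_chance_table_yields_negligible_coherence_scaling(self):
        tab = pd.DataFrame(
            {
                "coh1": [3.2, 6.4, 12.8, 3.2, 6.4, 12.8],
                "coh2": [np.nan, np.nan, np.nan, 3.2, 6.4, 12.8],
                "n_trials": [4000] * 6,
                "n_correct": [2000] * 6,
            }
        )
        res = fit(tab, seed=4, n_restarts=6)
        # with every condition at chance, the fitted sensitivity k * coh must
        # carry almost no tilt: predicted accuracies stay near 0.5
        assert np.all(np.abs(res.predictions["p_model"] - 0.5) < 0.02)

    def test_requires_informative_conditions(self):
        tab = pd.DataFrame(
            {"coh1": [0.0], "coh2": [np.nan], "n_trials": [100], "n_correct": [50]}
        )
        with pytest.raises(ValueError):
            fit(tab, seed=0)


class TestPRI:
    def test_equal_pulse_weights_give_zero_index(self, rng):
        coh = rng.choice([3.2, 6.4, 12.8], size=(20_000, 2))
        logit = -0.5 + 0.08 * coh.sum(axis=1)
        correct = rng.random(20_000) < 1 / (1 + np.exp(-logit))
        trials = pd.DataFrame(
            {"coh1": coh[:, 0], "coh2": coh[:, 1], "correct": correct.astype(int)}
        )
        assert abs(pri(trials)) < 0.1

    def test_second_pulse_only_gives_recency_limit(self, rng):
        coh = rng.choice([3.2, 6.4, 12.8], size=(20_000, 2))
        logit = -0.5 + 0.15 * coh[:, 1]
        correct = rng.random(20_000) < 1 / (1 + np.exp(-logit))
        trials = pd.DataFrame(
            {"coh1": coh[:, 0], "coh2": coh[:, 1], "correct": correct.astype(int)}
        )
        assert pri(trials) > 0.8

    def test_model_pri_reflects_barrier_height(self, fitted_params):
        """Lower barriers activate second-pulse transitions and push the
        index toward recency."""
        low_barrier = PulseParams(k=0.012, alpha=0.25, sigma=0.52, tau_s=0.4)
        high_barrier = PulseParams(k=0.012, alpha=1.2, sigma=0.52, tau_s=0.4)
        assert model_pri(low_barrier, 8000, seed=5) > model_pri(high_barrier, 8000, seed=5)

    def test_requires_varying_coherences(self):
        trials = pd.DataFrame({"coh1": [3.2] * 10, "coh2": [3.2] * 10,
                               "correct": [1] * 10})
        with pytest.raises(ValueError):
            pri(trials)


class TestDelayRobustness:
    def test_noise_bound_matches_printed_value(self, fitted_params):
        res = delay_robustness(fitted_params)
        assert round(res["sigma_i_max"], 2) == 0.32

    def test_attractor_memory_is_delay_flat(self, fitted_params):
        res = delay_robustness(fitted_params, delays_s=np.linspace(0, 1.08, 8))
        dwm = res["dwm_accuracy"]
        assert np.max(dwm) - np.min(dwm) < 0.01 * np.max(dwm)

    def test_diffusive_memory_decays_with_delay(self, fitted_params):
        res = delay_robustness(fitted_params, delays_s=np.linspace(0, 1.08, 8))
        assert np.all(np.diff(res["pi_accuracy"]) < 0)

    def test_implied_noise_split(self, fitted_params):
        """sigma_I^max / sigma_S at the fitted total noise is ~0.8."""
        res = delay_robustness(fitted_params)
        s_i = res["sigma_i_max"]
        s_s = np.sqrt(fitted_params.sigma**2 - s_i**2)
        assert round(s_i / s_s, 1) == 0.8

    def test_threshold_validated(self, fitted_params):
        with pytest.raises(ValueError):
            delay_robustness(fitted_params, threshold=0.0)
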