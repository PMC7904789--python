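"""Stimulus-generator contracts: exactness, moments, determinism."""

import numpy as np
import pytest
from scipy import stats

from flexcat import stimuli
from flexcat.stimuli import (
    StimulusSet,
    brightness_disc_frames,
    gaussian_frames,
    ou_currents,
    two_pulse_design,
    zero_integral_frames,
)


class TestGaussianFrames:
    def test_trial_sum_moments_match_closed_form(self):
        # sum over 10 frames of N(0.15, 0.58^2) is N(1.5, 10 * 0.58^2)
        st = gaussian_frames(5000, 10, mu=0.15, sigma_s=0.58, seed=7)
        sums = st.frames.sum(axis=1)
        exp_mean, exp_var = 1.5, 10 * 0.58**2
        assert abs(sums.mean() - exp_mean) < 4 * np.sqrt(exp_var / 5000)
        assert abs(sums.var() - exp_var) < 4 * exp_var * np.sqrt(2 / 4999)

    def test_grand_mean_and_sd(self):
        st = gaussian_frames(1000, 20, mu=0.0, sigma_s=1.0, seed=1)
        n = st.frames.size
        assert abs(st.frames.mean()) < 3 / np.sqrt(n)
        assert abs(st.frames.std() - 1.0) < 3 / np.sqrt(2 * n)

    def test_degenerate_noise_is_exact(self):
        st = gaussian_frames(17, 9, mu=0.5, sigma_s=0.0, seed=0)
        assert np.all(st.frames == 0.5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_frames(10, 10, 0.0, -0.1, seed=0)

    def test_identical_seed_is_bit_identical(self):
        a = gaussian_frames(50, 20, 0.1, 0.3, seed=42)
        b = gaussian_frames(50, 20, 0.1, 0.3, seed=42)
        assert np.array_equal(a.frames, b.frames)


class TestZeroIntegralFrames:
    def test_rows_exactly_zero_mean_and_exact_sd(self):
        st = zero_integral_frames(200, 37, sigma_s=0.58, seed=3)
        np.testing.assert_allclose(st.frames.mean(axis=1), 0.0, atol=1e-14)
        np.testing.assert_allclose(st.frames.std(axis=1), 0.58, rtol=1e-12)

    def test_two_frames_forced_to_plus_minus(self):
        st = zero_integral_frames(8, 2, sigma_s=1.0, seed=11)
        assert np.allclose(np.sort(st.frames, axis=1), [-1.0, 1.0])

    def test_pooled_distribution_is_gaussian(self):
        # after z-scoring, the pooled frames are close to N(0, sigma_s^2)
        st = zero_integral_frames(500, 40, sigma_s=0.3, seed=5)
        z = st.frames.ravel() / 0.3
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            zero_integral_frames(5, 1, 1.0, seed=0)


class TestBrightnessDiscs:
    def test_no_pulse_trial_mean_equals_generative_gap(self):
        st = brightness_disc_frames(50, 2.0, gen_mean_gap=0.3, frame_sd=0.0,
                                    pulse_prob=0.0, seed=2)
        np.testing.assert_allclose(st.frames.mean(axis=1), 0.3, atol=1e-14)

    def test_pulse_compensation_is_exact(self):
        # with a pulse in every trial, segment means sum to 5 * gap
        st = brightness_disc_frames(100, 2.0, gen_mean_gap=0.25, frame_sd=0.0,
                                    pulse_prob=1.0, pulse_size=0.7, seed=4)
        seg = st.frames.reshape(100, 5, -1).mean(axis=2)
        np.testing.assert_allclose(seg.sum(axis=1), 5 * 0.25, atol=1e-12)
        # and the pulse itself is visible in one segment
        assert np.all(np.abs(seg - 0.25).max(axis=1) > 0.5)

    def test_compensation_induces_anticorrelated_segments(self):
        st = brightness_disc_frames(10_000, 1.0, gen_mean_gap=0.0, frame_sd=0.1,
                                    pulse_prob=0.8, pulse_size=0.4, seed=6)
        seg = st.frames.reshape(10_000, 5, -1).mean(axis=2)
        dev = seg - seg.mean(axis=1, keepdims=True)
        lag1 = np.mean(dev[:, :-1] * dev[:, 1:])
        assert lag1 < 0

    def test_pulse_prob_validated(self):
        with pytest.raises(ValueError):
            brightness_disc_frames(5, 1.0, pulse_prob=1.5, seed=0)


class TestTwoPulseDesign:
    def test_default_condition_counts(self):
        df = two_pulse_design()
        doubles = df[df["coh2"].notna()]
        assert doubles.groupby(["coh1", "coh2"]).ngroups == 9
        assert df["coh2"].isna().sum() == 6  # single-pulse coherence levels

    def test_single_condition(self):
        df = two_pulse_design(coherences=[6.4], delays_ms=[120])
        assert len(df[df["coh2"].notna()]) == 1


class TestOUCurrents:
    def test_zero_noise_constant_traces(self):
        ou = ou_currents(mu=0.2, sigma_s=0.0, duration_s=0.1, i0=2.0, seed=0)
        assert np.all(ou.current_a == 2.0 * 1.2)
        assert np.all(ou.current_b == 2.0 * 0.8)

    def test_autocorrelation_time_near_20_ms(self):
        ou = ou_currents(mu=0.0, sigma_s=1.0, duration_s=60.0, dt_ms=1.0,
                         tau_stim_ms=20.0, seed=9)
        z = ou.current_a[0] - 1.0
        lags_ms = np.arange(1, 15)
        acf = np.array([np.corrcoef(z[:-k], z[k:])[0, 1] for k in lags_ms])
        tau_fit = -1.0 / np.polyfit(lags_ms, np.log(np.abs(acf)), 1)[0]
        assert abs(tau_fit - 20.0) / 20.0 < 0.10

    def test_symmetric_means_at_zero_mu(self):
        ou = ou_currents(mu=0.0, sigma_s=0.5, duration_s=20.0, dt_ms=1.0, seed=10)
        assert abs(ou.current_a.mean() - ou.current_b.mean()) < 0.05

    def test_stationary_sd_matches_sigma(self):
        ou = ou_currents(mu=0.0, sigma_s=0.7, duration_s=50.0, dt_ms=1.0, seed=12)
        assert abs(ou.current_a.std() - 0.7) < 0.05


class TestStreamsAndSerialization:
    def test_stimulus_stream_independent_of_internal(self):
        """Regenerating stimuli must not perturb internal-noise draws."""
        from flexcat._rng import rng_for

        before = rng_for(99, "internal").standard_normal(5)
        gaussian_frames(100, 10, 0.0, 1.0, seed=99)  # stimulus-role draws
        after = rng_for(99, "internal").standard_normal(5)
        assert np.array_equal(before, after)

    def test_roles_are_distinct_streams(self):
        from flexcat._rng import rng_for

        a = rng_for(1, "stimulus").standard_normal(8)
        b = rng_for(1, "internal").standard_normal(8)
        assert not np.allclose(a, b)

    def test_csv_roundtrip(self, tmp_path):
        st = zero_integral_frames(12, 8, 0.4, seed=13)
        path = tmp_path / "stim.csv"
        st.to_csv(path)
        back = StimulusSet.from_csv(path)
        np.testing.assert_allclose(back.frames, st.frames, rtol=1e-12)
        assert back.kind == "zero_integral"
        assert back.frame_duration == st.frame_duration

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            StimulusSet(np.zeros((2, 2)), 0.1, np.zeros(2), 1.0, "nope", 0)
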