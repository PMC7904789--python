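"""Integration-engine contracts: forces, bounds, bookkeeping, convergence."""

import numpy as np
import pytest

from flexcat import stimuli, theory
from flexcat.models import (
    BoundSpec,
    IntegratorConfig,
    canonical_model,
    run_psychometric,
    simulate,
)
from flexcat.potentials import PotentialSpec, SingleWellError, double_well, flat, linear


class TestPotential:
    @pytest.mark.parametrize(
        "pot, x, expected",
        [
            (double_well(0.0, 0.5), 0.5, 0.0),  # x = sqrt(alpha/2) is a fixed point
            (flat(), 0.37, 0.0),
            (double_well(0.1, 1.0), 0.3, 0.1 + 0.6 - 0.108),
        ],
    )
    def test_drift_hand_values(self, pot, x, expected):
        assert np.isclose(pot.drift(x), expected)

    def test_exact_fixed_points_match_bracket_oracle(self):
        pot = double_well(0.1, 1.0)
        x_e, x_u, x_c = pot.fixed_points()
        # independent oracle: dense-grid sign-change bracketing of phi'
        grid = np.linspace(-2, 2, 400_001)
        dphi = -pot.drift(grid)
        sign_change = np.nonzero(np.diff(np.sign(dphi)) != 0)[0]
        assert len(sign_change) == 3
        from scipy.optimize import brentq

        roots = [
            brentq(lambda x: -pot.drift(x), grid[i], grid[i + 1], xtol=1e-14)
            for i in sign_change
        ]
        np.testing.assert_allclose([x_e, x_u, x_c], roots, atol=1e-10)

    def test_unstable_point_small_tilt_expansion(self):
        # x_U ~ -mu/(2 alpha) to first order in mu
        pot = double_well(0.01, 0.5)
        _, x_u, _ = pot.fixed_points()
        assert np.isclose(x_u, -0.01 / (2 * 0.5), atol=2e-4)

    def test_single_well_beyond_critical_tilt(self):
        with pytest.raises(SingleWellError):
            double_well(0.2, 0.5).fixed_points()  # mu_C(0.5) = 0.125

    def test_perturbative_points_defined_beyond_bifurcation(self):
        # mu_C(0.5) = 0.125; the exact cubic has one root there but the O(mu)
        # expansion still yields an ordered triple for moderate extrapolation
        x_e, x_u, x_c = double_well(0.2, 0.5).fixed_points("perturbative")
        assert x_e < x_u < x_c


class TestEngine:
    def test_noiseless_perfect_integrator_is_exact(self):
        st = stimuli.gaussian_frames(5, 40, mu=0.5, sigma_s=0.0, seed=1)
        ens = simulate(st, flat(), None, IntegratorConfig(seed=1))
        np.testing.assert_allclose(ens.x_final, 0.5 * st.duration / 0.2, rtol=1e-12)

    def test_deterministic_double_well_always_correct(self):
        st = stimuli.gaussian_frames(50, 200, mu=0.15, sigma_s=0.0, seed=2)
        ens = simulate(st, double_well(0.15, 1.0), None, IntegratorConfig(seed=2))
        assert ens.accuracy() == 1.0

    def test_sign_symmetry_flips_choices(self):
        """(mu, stimuli) -> (-mu, -stimuli) must flip every choice."""
        st = stimuli.gaussian_frames(500, 100, mu=0.1, sigma_s=0.4, seed=3)
        neg = stimuli.StimulusSet(
            frames=-st.frames, frame_duration=st.frame_duration,
            mu_per_trial=-st.mu_per_trial, sigma_s=st.sigma_s,
            kind=st.kind, seed=st.seed, coupling=st.coupling,
        )
        cfg = IntegratorConfig(sigma_i=0.0, seed=3)
        a = simulate(st, double_well(0.1, 1.0), None, cfg)
        b = simulate(neg, double_well(-0.1, 1.0), None, cfg)
        assert np.array_equal(a.choices, -b.choices)

    def test_absorbing_bound_freezes_state(self):
        st = stimuli.gaussian_frames(300, 100, mu=0.0, sigma_s=0.8, seed=4)
        ens = simulate(st, linear(0.0), BoundSpec("absorbing", 0.5),
                       IntegratorConfig(sigma_i=0.1, seed=4))
        inside = np.abs(ens.x_final) < 0.5
        at_bound = np.isclose(np.abs(ens.x_final), 0.5)
        assert np.all(inside | at_bound)
        assert at_bound.any()

    def test_reflecting_bound_clamps(self):
        st = stimuli.gaussian_frames(300, 100, mu=0.0, sigma_s=0.8, seed=5)
        ens = simulate(st, linear(0.0), BoundSpec("reflecting", 0.5),
                       IntegratorConfig(sigma_i=0.1, seed=5))
        assert np.all(np.abs(ens.x_final) <= 0.5 + 1e-12)

    def test_tie_break_is_seeded_coin(self):
        st = stimuli.gaussian_frames(400, 10, mu=0.0, sigma_s=0.0, seed=6)
        ens = simulate(st, flat(), None, IntegratorConfig(seed=6))
        assert set(np.unique(ens.choices)) == {-1, 1}
        again = simulate(st, flat(), None, IntegratorConfig(seed=6))
        assert np.array_equal(ens.choices, again.choices)

    def test_frame_grid_must_divide_dt(self):
        st = stimuli.gaussian_frames(5, 10, 0.0, 0.1, seed=0, frame_duration=0.003)
        with pytest.raises(ValueError, match="integer multiple"):
            simulate(st, flat(), None, IntegratorConfig(seed=0))

    def test_first_visit_frequency_matches_splitting_probability(self):
        """Empirical first-visit stats agree with the exact splitting integral."""
        pot = double_well(0.15, 1.0)
        p0 = theory.first_visit_probability(pot, 0.4, method="quadrature")
        st = stimuli.gaussian_frames(6000, 200, mu=0.15, sigma_s=0.4, seed=7)
        ens = simulate(st, pot, None, IntegratorConfig(seed=7))
        visited = ens.first_visit != 0
        frac = np.mean(ens.first_visit[visited] == 1)
        se = np.sqrt(p0 * (1 - p0) / visited.sum())
        assert abs(frac - p0) < 2 * se

    def test_halving_dt_changes_accuracy_by_less_than_2se(self):
        pot = double_well(0.15, 1.0)
        accs = []
        n = 4000
        for dt in (0.005, 0.0025):
            st = stimuli.gaussian_frames(n, 100, 0.15, 0.4, seed=8,
                                         frame_duration=0.005)
            ens = simulate(st, pot, None, IntegratorConfig(dt=dt, seed=8))
            accs.append(ens.accuracy())
        se = np.sqrt(accs[0] * (1 - accs[0]) / n)
        assert abs(accs[0] - accs[1]) < 2 * np.sqrt(2) * se

    def test_absorption_probability_matches_fine_step_oracle(self):
        """Coarse-step first-passage probability vs a 10x finer-dt oracle."""
        def p_absorbed(dt, seed, n=4000):
            st = stimuli.gaussian_frames(n, 120, 0.0, 0.0, seed=seed,
                                         frame_duration=0.006)
            ens = simulate(st, linear(0.0), BoundSpec("absorbing", 0.4),
                           IntegratorConfig(dt=dt, sigma_i=0.5, seed=seed))
            return np.mean(np.isclose(np.abs(ens.x_final), 0.4)), n

        p_coarse, n = p_absorbed(0.006, seed=9)
        p_fine, _ = p_absorbed(0.0006, seed=10)
        se = np.sqrt(p_fine * (1 - p_fine) / n)
        # Euler first-passage converges slowly (missed intra-step excursions);
        # allow the documented 2-SE band around the fine-step oracle plus the
        # O(sqrt(dt)) crossing bias bound
        assert abs(p_coarse - p_fine) < 2 * np.sqrt(2) * se + 0.6 * np.sqrt(0.006 / 0.2)


class TestPsychometric:
    def test_zero_mean_cell_is_at_chance(self):
        df = run_psychometric("dwm", [0.0], [0.4], [1.0], 400, seed=11, alpha=1.0)
        p = df["p_correct"].iloc[0]
        assert abs(p - 0.5) < 3 * df["se"].iloc[0]

    def test_requires_minimum_trials(self):
        with pytest.raises(ValueError):
            run_psychometric("pi", [0.1], [0.2], [1.0], 10, seed=0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            canonical_model("bogus")
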