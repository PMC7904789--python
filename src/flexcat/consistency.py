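"""Double-pass choice consistency.

Consistency is the probability that two presentations of the exact same
stimulus realization, with independent internal-noise draws, yield the same
choice.  It is 1 when the decision is a deterministic function of the
stimulus (sigma_I = 0) and 0.5 when the stimulus has no influence at all.
Only stimuli with exactly zero integrated evidence are used, so consistency
cannot rise trivially through trials whose accumulated evidence happens to
deviate far from zero.

Per stimulus, consistency p^2 + (1-p)^2 (p the per-stimulus probability of a
rightward choice) is estimated without small-sample bias by the U-statistic:
the fraction of concordant unordered pass pairs,
(n_R (n_R - 1) + n_L (n_L - 1)) / (n (n - 1)).

The companion diagnostic compares the per-trial attractor-switch probability
with and without internal noise on identical stimuli: the consistency dip
occurs where switches need the cooperation of internal and stimulus noise,
i.e. where that difference peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BoundSpec, IntegratorConfig, simulate
from .potentials import PotentialSpec
from .stimuli import StimulusSet, zero_integral_frames


class ProtocolError(ValueError):
    pass


@dataclass
class ConsistencyResult:
    sigma_s_grid: np.ndarray
    consistency: np.ndarray
    per_stimulus: np.ndarray | None = None  # (n_sigma, n_stimuli)
    sem: np.ndarray | None = None
    n_stimuli: int = 0
    n_passes: int = 0


def pair_consistency(choices: np.ndarray) -> np.ndarray:
    """Unbiased per-stimulus consistency from a (n_stimuli, n_passes) choice
    matrix: fraction of concordant unordered pass pairs."""
    choices = np.asarray(choices)
    if choices.ndim != 2 or choices.shape[1] < 2:
        raise ValueError("need at least two passes per stimulus")
    n = choices.shape[1]
    n_r = (choices > 0).sum(axis=1)
    n_l = n - n_r
    return (n_r * (n_r - 1) + n_l * (n_l - 1)) / (n * (n - 1))


def double_pass(
    potential: PotentialSpec,
    config: IntegratorConfig,
    sigma_s_grid,
    n_stimuli: int = 200,
    n_passes: int = 20,
    seed: int | None = None,
    duration_s: float = 0.5,
    bounds: BoundSpec | None = None,
    stimuli_by_sigma: list[StimulusSet] | None = None,
) -> ConsistencyResult:
    """Double-pass consistency across a sigma_S sweep.

    Each of ``n_stimuli`` zero-integral stimuli is presented ``n_passes``
    times with independent internal-noise draws (default 20 passes rather
    than the experimental 2: the generative process is under our control, so
    more passes sharpen the per-stimulus estimate; the estimator itself is
    unbiased for any n_passes >= 2).  Pass ``n_passes=2`` for the strict
    experimental double-pass protocol.
    """
    if n_passes < 2:
        raise ValueError("need at least two passes")
    seed = config.seed if seed is None else seed
    sigma_s_grid = np.atleast_1d(np.asarray(sigma_s_grid, dtype=float))
    n_frames = int(round(duration_s / config.dt))
    per_stim = np.empty((sigma_s_grid.size, n_stimuli))
    for i, sig_s in enumerate(sigma_s_grid):
        if stimuli_by_sigma is not None:
            stim = stimuli_by_sigma[i]
            if stim.kind != "zero_integral":
                raise ProtocolError(
                    "double-pass protocol requires zero-integral stimuli"
                )
            n_stimuli = stim.n_trials
            if i == 0:
                per_stim = np.empty((sigma_s_grid.size, n_stimuli))
        else:
            stim = zero_integral_frames(
                n_stimuli, n_frames, sig_s, seed,
                frame_duration=config.dt, stream_index=i,
            )
        # repeat each stimulus n_passes times; internal noise is fresh per pass
        rep = StimulusSet(
            frames=np.repeat(stim.frames, n_passes, axis=0),
            frame_duration=stim.frame_duration,
            mu_per_trial=np.repeat(stim.mu_per_trial, n_passes),
            sigma_s=stim.sigma_s,
            kind=stim.kind,
            seed=stim.seed,
            coupling=stim.coupling,
        )
        cfg = IntegratorConfig(
            tau=config.tau, dt=config.dt, sigma_i=config.sigma_i,
            x0=config.x0, seed=seed, stream_index=i,
        )
        ens = simulate(rep, potential, bounds, cfg)
        choices = ens.choices.reshape(n_stimuli, n_passes)
        per_stim[i] = pair_consistency(choices)
    return ConsistencyResult(
        sigma_s_grid=sigma_s_grid,
        consistency=per_stim.mean(axis=1),
        per_stimulus=per_stim,
        sem=per_stim.std(axis=1, ddof=1) / np.sqrt(per_stim.shape[1]),
        n_stimuli=n_stimuli,
        n_passes=n_passes,
    )


def transition_diag(
    potential: PotentialSpec,
    sigma_s_grid,
    sigma_i: float,
    n_trials: int = 2000,
    seed: int = 0,
    duration_s: float = 0.5,
    tau: float = 0.2,
    dt: float | None = None,
) -> dict:
    """|p_switch(sigma_S, sigma_I) - p_switch(sigma_S, 0)| over a sigma_S sweep.

    The per-trial probability of at least one attractor switch is estimated
    on identical zero-integral stimuli with and without internal noise; the
    difference localizes the cooperative-transition regime.
    """
    if potential.family != "double_well":
        raise ValueError("the switch diagnostic is defined for the double well")
    sigma_s_grid = np.atleast_1d(np.asarray(sigma_s_grid, dtype=float))
    cfg0 = IntegratorConfig(tau=tau, dt=dt, seed=seed)
    n_frames = int(round(duration_s / cfg0.dt))
    p_with = np.empty(sigma_s_grid.size)
    p_without = np.empty(sigma_s_grid.size)
    for i, sig_s in enumerate(sigma_s_grid):
        stim = zero_integral_frames(
            n_trials, n_frames, sig_s, seed, frame_duration=cfg0.dt, stream_index=i
        )
        for slot, s_i in ((p_with, sigma_i), (p_without, 0.0)):
            cfg = IntegratorConfig(
                tau=tau, dt=dt, sigma_i=s_i, seed=seed, stream_index=i
            )
            ens = simulate(stim, potential, None, cfg)
            slot[i] = float(np.mean(ens.n_transitions > 0))
    return {
        "sigma_s_grid": sigma_s_grid,
        "p_with": p_with,
        "p_without": p_without,
        "delta_p": np.abs(p_with - p_without),
    }
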