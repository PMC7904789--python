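"""Euler-Maruyama integration of the decision-variable diffusion.

One engine covers the perfect integrator (flat potential, no bounds), the
drift-diffusion models with absorbing or reflecting bounds (linear potential),
and the double-well attractor model.  The update is

    x(t+dt) = x(t) - (dt/tau) * phi'(x)
              + sqrt(dt/tau) * (sigma_I xi_I + sigma_S xi_S)

with dt = tau/40 by default.  Frame-based stimuli are held piecewise-constant
within a frame: noise-coupled ensembles contribute their zero-mean residual
once per frame with the sqrt(frame_duration/tau) scaling (so the integrated
stimulus variance matches the white-noise process regardless of dt), while
drift-coupled ensembles (e.g. brightness differences) act as the momentary
tilt of the potential.

The choice is the sign of x at stimulus offset; for the double well the
engine also records which attractor was visited first and every subsequent
attractor switch, using a full-hysteresis detector (a switch requires
crossing from one attractor position all the way to the other, preventing
chatter near the barrier top).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for
from .potentials import PotentialSpec, SingleWellError, double_well, flat, linear
from .stimuli import StimulusSet, gaussian_frames


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoundSpec:
    """Decision bounds: ``none`` (free diffusion), ``absorbing`` (x frozen on
    first |x| >= magnitude) or ``reflecting`` (x clamped to [-B, B])."""

    kind: str = "none"
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "absorbing", "reflecting"):
            raise ValueError(f"unknown bound kind {self.kind!r}")
        if self.kind != "none" and self.magnitude <= 0:
            raise ValueError("bound magnitude must be positive")


@dataclass(frozen=True)
class IntegratorConfig:
    """Numerical configuration of the stochastic integrator.

    ``tau`` is the integration time constant (200 ms default), ``dt`` the Euler
    step (tau/40 default, must not exceed tau/10), ``sigma_i`` the internal
    noise magnitude, ``x0`` the initial condition and ``seed`` the master seed
    of the run (internal noise draws from the "internal" stream).
    """

    tau: float = 0.2
    dt: float | None = None
    sigma_i: float = 0.0
    x0: float = 0.0
    seed: int = 0
    record_trajectories: bool = False
    record_transition_times: bool = False
    stream_index: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        dt = self.tau / 40.0 if self.dt is None else self.dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > self.tau / 10.0 + 1e-12:
            raise ValueError("dt must not exceed tau/10 (Euler stability)")
        if self.sigma_i < 0:
            raise ValueError("sigma_i must be non-negative")
        object.__setattr__(self, "dt", dt)


@dataclass
class TrialEnsemble:
    """Summaries of a batch of simulated decision trials.

    ``choices`` is +/-1 per trial (sign of x at offset, seeded fair coin at an
    exact tie).  For the double-well model, ``first_visit`` is the sign of the
    first attractor basin entered (0 if none was reached) and
    ``n_transitions`` counts full barrier crossings between attractors;
    ``transition_times`` (opt-in) lists signed switch times per trial, the
    sign being the attractor entered.  ``trajectories`` (opt-in) holds the
    full x(t) record including the initial condition.
    """

    choices: np.ndarray
    x_final: np.ndarray
    mu_per_trial: np.ndarray
    first_visit: np.ndarray | None = None
    n_transitions: np.ndarray | None = None
    transition_times: list | None = None
    trajectories: np.ndarray | None = None
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.choices.size

    def accuracy(self) -> float:
        """Fraction of choices matching sign(mu); P(rightward) where mu = 0."""
        mu = self.mu_per_trial
        target = np.where(mu == 0, 1, np.sign(mu))
        return float(np.mean(self.choices == target))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "choice": self.choices,
                "x_final": self.x_final,
            }
        )
        df["first_visit"] = 0 if self.first_visit is None else self.first_visit
        df["n_transitions"] = 0 if self.n_transitions is None else self.n_transitions
        return df


def _attractor_thresholds(potential: PotentialSpec, mu_ref: float):
    """Attractor positions used by the hysteresis detector, or None."""
    if potential.family != "double_well":
        return None
    ref = PotentialSpec("double_well", mu=mu_ref, alpha=potential.alpha)
    try:
        x_e, _, x_c = ref.fixed_points("exact")
    except SingleWellError:
        return None
    return x_e, x_c


def simulate(
    stimuli: StimulusSet,
    potential: PotentialSpec,
    bounds: BoundSpec | None = None,
    config: IntegratorConfig | None = None,
) -> TrialEnsemble:
    """Integrate the diffusion for every trial of a stimulus ensemble.

    The tilt of the potential is read from the stimuli: the per-trial
    generative mean for noise-coupled ensembles, the momentary frame value for
    drift-coupled ensembles (in which case no separate stimulus noise is
    added; the fluctuations live in the frames themselves).
    """
    bounds = bounds or BoundSpec()
    config = config or IntegratorConfig()
    dt, tau = config.dt, config.tau

    steps_per_frame = stimuli.frame_duration / dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9 or steps_per_frame < 1:
        raise ValueError(
            f"frame duration {stimuli.frame_duration} s is not an integer "
            f"multiple of dt = {dt} s"
        )
    steps_per_frame = int(round(steps_per_frame))
    n_trials, n_frames = stimuli.n_trials, stimuli.n_frames
    n_steps = n_frames * steps_per_frame

    rng = rng_for(config.seed, "internal", config.stream_index)
    x = np.full(n_trials, float(config.x0))
    mu_i = stimuli.mu_per_trial
    noise_coupled = stimuli.coupling == "noise"
    if noise_coupled:
        fluct = stimuli.fluctuations() * np.sqrt(stimuli.frame_duration / tau)

    thresholds = _attractor_thresholds(potential, float(np.mean(mu_i)))
    track = thresholds is not None
    if track:
        x_e, x_c = thresholds
        state = np.zeros(n_trials, dtype=np.int8)
        first_visit = np.zeros(n_trials, dtype=np.int8)
        n_transitions = np.zeros(n_trials, dtype=np.int64)
        transition_times = [[] for _ in range(n_trials)] if config.record_transition_times else None

    trajectories = None
    if config.record_trajectories:
        trajectories = np.empty((n_trials, n_steps + 1))
        trajectories[:, 0] = x

    absorbing = bounds.kind == "absorbing"
    reflecting = bounds.kind == "reflecting"
    active = np.ones(n_trials, dtype=bool) if absorbing else None
    sqrt_step = np.sqrt(dt / tau)

    for step in range(n_steps):
        frame = step // steps_per_frame
        if noise_coupled:
            drive = mu_i
        else:
            drive = stimuli.frames[:, frame]
        force = drive + potential.internal_force(x)
        dx = (dt / tau) * force
        if config.sigma_i > 0:
            dx = dx + sqrt_step * config.sigma_i * rng.standard_normal(n_trials)
        if noise_coupled and step % steps_per_frame == 0:
            dx = dx + fluct[:, frame]
        if absorbing:
            x = np.where(active, x + dx, x)
            hit = active & (np.abs(x) >= bounds.magnitude)
            if np.any(hit):
                x[hit] = np.sign(x[hit]) * bounds.magnitude
                active[hit] = False
        else:
            x = x + dx
            if reflecting:
                np.clip(x, -bounds.magnitude, bounds.magnitude, out=x)

        if track:
            mask = active if absorbing else None
            for sign_, thresh, cmp in ((1, x_c, np.greater_equal), (-1, x_e, np.less_equal)):
                crossed = cmp(x, thresh) & (state != sign_)
                if mask is not None:
                    # absorbed trials keep their state: no further transitions
                    crossed &= mask | (state == 0)
                if np.any(crossed):
                    fresh = crossed & (state == 0)
                    switch = crossed & (state == -sign_)
                    first_visit[fresh] = sign_
                    n_transitions[switch] += 1
                    if transition_times is not None:
                        t_now = (step + 1) * dt
                        for idx in np.nonzero(switch)[0]:
                            transition_times[idx].append(sign_ * t_now)
                    state[crossed] = sign_
        if trajectories is not None:
            trajectories[:, step + 1] = x

    if np.isnan(x).any():
        bad = int(np.nonzero(np.isnan(x))[0][0])
        raise IntegrationError(
            f"NaN in trajectory of trial {bad}: dt = {dt} too large for this potential"
        )

    choices = np.sign(x).astype(np.int8)
    ties = choices == 0
    if np.any(ties):
        choices[ties] = np.where(rng.random(int(ties.sum())) < 0.5, 1, -1)

    return TrialEnsemble(
        choices=choices,
        x_final=x,
        mu_per_trial=mu_i.copy(),
        first_visit=first_visit if track else None,
        n_transitions=n_transitions if track else None,
        transition_times=transition_times if track and config.record_transition_times else None,
        trajectories=trajectories,
        times=np.arange(n_steps + 1) * dt if trajectories is not None else None,
        meta={
            "potential": potential,
            "bounds": bounds,
            "dt": dt,
            "tau": tau,
            "sigma_i": config.sigma_i,
            "duration": n_steps * dt,
        },
    )


# ---------------------------------------------------------------------------
# model presets and psychometric sweeps
# ---------------------------------------------------------------------------

MODEL_NAMES = ("pi", "ddma", "ddmr", "dwm")


def canonical_model(
    name: str, mu: float = 0.0, alpha: float = 1.0, bound: float = 1.0
) -> tuple[PotentialSpec, BoundSpec]:
    """(potential, bounds) for a named model: pi, ddma, ddmr, or dwm.

    The bound magnitude B for the bounded drift-diffusion models defaults to 1
    in evidence units (only the scaling of the sigmas relative to B matters).
    """
    name = name.lower()
    if name == "pi":
        return flat(), BoundSpec("none")
    if name == "ddma":
        return linear(mu), BoundSpec("absorbing", bound)
    if name == "ddmr":
        return linear(mu), BoundSpec("reflecting", bound)
    if name == "dwm":
        return double_well(mu, alpha), BoundSpec("none")
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def run_psychometric(
    model: str,
    mu_grid,
    sigma_s_grid,
    T_grid,
    n_trials: int,
    seed: int,
    sigma_i: float = 0.0,
    alpha: float = 1.0,
    bound: float = 1.0,
    tau: float = 0.2,
    dt: float | None = None,
    max_chunk_elements: int = 40_000_000,
) -> pd.DataFrame:
    """Accuracy surface P(mu, sigma_s, T) for one model.

    Each cell simulates ``n_trials`` (>= 100) Gaussian-frame trials with its
    own stimulus and internal-noise substreams and reports the fraction of
    choices matching sign(mu) -- P(rightward) in mu = 0 cells -- plus the
    binomial standard error.
    """
    if n_trials < 100:
        raise ValueError("need at least 100 trials per cell")
    rows = []
    cell = 0
    for T in np.atleast_1d(T_grid):
        for mu in np.atleast_1d(mu_grid):
            for sig_s in np.atleast_1d(sigma_s_grid):
                cell += 1
                cfg = IntegratorConfig(
                    tau=tau, dt=dt, sigma_i=sigma_i, seed=seed, stream_index=cell
                )
                n_frames = int(round(T / cfg.dt))
                chunk = max(1, min(n_trials, max_chunk_elements // max(n_frames, 1)))
                n_correct = 0
                done = 0
                sub = 0
                while done < n_trials:
                    n_now = min(chunk, n_trials - done)
                    stim = gaussian_frames(
                        n_now, n_frames, mu, sig_s, seed,
                        frame_duration=cfg.dt, stream_index=cell * 1000 + sub,
                    )
                    pot, bnd = canonical_model(model, mu, alpha, bound)
                    cfg_sub = IntegratorConfig(
                        tau=tau, dt=dt, sigma_i=sigma_i, seed=seed,
                        stream_index=cell * 1000 + sub,
                    )
                    ens = simulate(stim, pot, bnd, cfg_sub)
                    n_correct += int(round(ens.accuracy() * n_now))
                    done += n_now
                    sub += 1
                p = n_correct / n_trials
                rows.append(
                    {
                        "model": model,
                        "mu": mu,
                        "sigma_s": sig_s,
                        "T": T,
                        "n": n_trials,
                        "p_correct": p,
                        "se": np.sqrt(p * (1 - p) / n_trials),
                    }
                )
    return pd.DataFrame(rows)
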