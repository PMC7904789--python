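"""Synthetic stimulus ensembles for evidence-integration experiments.

Every analysis in the package consumes frame-based evidence traces.  A
:class:`StimulusSet` stores a (trial x frame) matrix of evidence values plus
the per-trial generative mean, and declares how the frames couple to the
stochastic integrator:

* ``coupling="noise"`` -- the frames are the discretized stimulus-fluctuation
  process sigma_S * xi_S(t): the engine applies the per-trial mean ``mu_i`` as
  drift and the zero-mean residual with the sqrt(frame_duration / tau) noise
  scaling.  Used for the Gaussian and exactly-zero-integral ensembles, whose
  frame grid normally coincides with the integration step.
* ``coupling="drift"`` -- the frames ARE the momentary evidence (e.g. the
  brightness difference between two discs, 100 ms frames): the engine uses the
  frame value as the time-varying tilt of the potential and adds no separate
  stimulus noise.

Kinds
-----
``gaussian``
    i.i.d. Normal(mu, sigma_s^2) frames, the discrete analogue of white
    stimulus noise around a constant mean drift.
``zero_integral``
    each row z-scored and rescaled so that its sample mean is exactly 0 and
    its sample standard deviation exactly sigma_s -- stimuli carrying no net
    evidence, used for choice-consistency experiments.
``brightness_discs``
    net-evidence traces of a two-disc brightness discrimination: 100 ms
    frames, five equal segments, an evidence pulse in a random segment of
    ``pulse_prob`` of the trials, exactly compensated in the remaining
    segments (which makes segment deviations anticorrelated).
``two_pulse``
    condition tables for the two-pulse motion design (built by
    :func:`two_pulse_design`; trial-level traces are not needed because the
    working-memory analysis is closed-form).
``ou_current``
    paired Ornstein-Uhlenbeck stimulus currents for the spiking network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for

KINDS = ("gaussian", "zero_integral", "brightness_discs", "two_pulse", "ou_current")

#: default frame grid of the stochastic integrator (tau/40 with tau = 200 ms)
DEFAULT_FRAME_S = 0.005


@dataclass(frozen=True)
class StimulusSet:
    """Per-trial evidence traces with a common frame grid.

    Attributes
    ----------
    frames
        (n_trials, n_frames) evidence values, arbitrary evidence units.
    frame_duration
        seconds per frame; all trials share the grid.
    mu_per_trial
        generative mean evidence of each trial.
    sigma_s
        nominal fluctuation magnitude of the ensemble.
    kind, coupling, seed
        provenance tags (see module docstring).
    """

    frames: np.ndarray
    frame_duration: float
    mu_per_trial: np.ndarray
    sigma_s: float
    kind: str
    seed: int
    coupling: str = "noise"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.coupling not in ("noise", "drift"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        object.__setattr__(
            self, "mu_per_trial", np.asarray(self.mu_per_trial, dtype=float)
        )
        if self.frames.ndim != 2:
            raise ValueError("frames must be a (n_trials, n_frames) matrix")
        if self.mu_per_trial.shape != (self.frames.shape[0],):
            raise ValueError("mu_per_trial must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_duration

    @property
    def times(self) -> np.ndarray:
        """Frame centers, seconds from stimulus onset."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def fluctuations(self) -> np.ndarray:
        """Frames with the per-trial generative mean removed."""
        return self.frames - self.mu_per_trial[:, None]

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the trial x frame matrix as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            self.frames, columns=[f"{t:.6f}" for t in self.times]
        )
        df.insert(0, "mu", self.mu_per_trial)
        df.to_csv(path, index_label="trial")
        sidecar = {
            "frame_duration": self.frame_duration,
            "sigma_s": self.sigma_s,
            "kind": self.kind,
            "seed": self.seed,
            "coupling": self.coupling,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusSet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, index_col="trial")
        mu = df.pop("mu").to_numpy()
        return cls(
            frames=df.to_numpy(),
            frame_duration=sidecar["frame_duration"],
            mu_per_trial=mu,
            sigma_s=sidecar["sigma_s"],
            kind=sidecar["kind"],
            seed=sidecar["seed"],
            coupling=sidecar["coupling"],
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gaussian_frames(
    n_trials: int,
    n_frames: int,
    mu: float,
    sigma_s: float,
    seed: int,
    frame_duration: float = DEFAULT_FRAME_S,
    stream_index: int = 0,
) -> StimulusSet:
    """Frame-wise i.i.d. Gaussian evidence: S = mu + sigma_s * xi per frame."""
    if sigma_s < 0:
        raise ValueError("sigma_s must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = rng_for(seed, "stimulus", stream_index)
    frames = mu + sigma_s * rng.standard_normal((n_trials, n_frames))
    return StimulusSet(
        frames=frames,
        frame_duration=frame_duration,
        mu_per_trial=np.full(n_trials, float(mu)),
        sigma_s=float(sigma_s),
        kind="gaussian",
        seed=seed,
    )


def zero_integral_frames(
    n_trials: int,
    n_frames: int,
    sigma_s: float,
    seed: int,
    frame_duration: float = DEFAULT_FRAME_S,
    stream_index: int = 0,
) -> StimulusSet:
    """Stimuli whose integrated evidence is exactly zero.

    Each row of Gaussian draws is z-scored (population sd, ddof=0) and scaled
    by sigma_s, so that every trial has sample mean exactly 0 and sample
    standard deviation exactly sigma_s.  A degenerate draw with zero sample
    variance is redrawn from the next substream (the event is recorded in
    ``meta["redraws"]``).
    """
    if n_frames < 2:
        raise ValueError("z-scoring needs at least two frames")
    if sigma_s < 0:
        raise ValueError("sigma_s must be non-negative")
    rng = rng_for(seed, "stimulus", stream_index)
    y = rng.standard_normal((n_trials, n_frames))
    redraws = 0
    sd = y.std(axis=1)
    while np.any(sd == 0.0):  # essentially impossible, but the contract is exact
        redraws += 1
        bad = sd == 0.0
        y[bad] = rng_for(seed, "stimulus", stream_index + 1000 + redraws).standard_normal(
            (int(bad.sum()), n_frames)
        )
        sd = y.std(axis=1)
    frames = sigma_s * (y - y.mean(axis=1, keepdims=True)) / sd[:, None]
    return StimulusSet(
        frames=frames,
        frame_duration=frame_duration,
        mu_per_trial=np.zeros(n_trials),
        sigma_s=float(sigma_s),
        kind="zero_integral",
        seed=seed,
        meta={"redraws": redraws},
    )


def brightness_disc_frames(
    n_trials: int,
    duration_s: float,
    gen_mean_gap: float = 0.2,
    frame_sd: float = 0.4,
    pulse_prob: float = 0.8,
    pulse_size: float = 0.4,
    seed: int = 0,
    n_segments: int = 5,
    remove_mean: bool = False,
    stream_index: int = 0,
) -> StimulusSet:
    """Net-evidence traces of the two-disc brightness discrimination.

    The brightness of each disc is redrawn every 100 ms from a Gaussian; the
    trace stored here is the right-minus-left difference, whose generative
    mean is ``gen_mean_gap`` and whose per-frame sd is ``frame_sd``.  In
    ``pulse_prob`` of the trials one of ``n_segments`` equal segments receives
    a congruent or incongruent evidence pulse of size ``pulse_size`` which is
    exactly compensated in the remaining segments, so the sum of the segment
    means always equals n_segments * gen_mean_gap (anticorrelated frames).

    With ``remove_mean=True`` the generative mean gap is subtracted, leaving a
    zero-generative-mean trace (the form used for reverse correlation).

    The luminance-to-evidence scaling of the original display is not fixed by
    anything in this package, so the generative defaults are structural
    choices: they put the driven double-well observer (alpha = 0.8,
    sigma_I = 0.3, tau = 200 ms) at intermediate accuracy, inside the regime
    where the kernel crosses from primacy to recency as the duration grows.
    """
    if not 0.0 <= pulse_prob <= 1.0:
        raise ValueError("pulse_prob must lie in [0, 1]")
    frame_duration = 0.1  # the 100 ms display frame of the task
    n_frames = int(round(duration_s / frame_duration))
    if n_frames < n_segments or n_frames % n_segments:
        raise ValueError(
            f"duration {duration_s} s does not divide into {n_segments} equal "
            f"segments of 100 ms frames"
        )
    per_seg = n_frames // n_segments
    rng = rng_for(seed, "stimulus", stream_index)
    frames = gen_mean_gap + frame_sd * rng.standard_normal((n_trials, n_frames))

    has_pulse = rng.random(n_trials) < pulse_prob
    pulse_seg = rng.integers(0, n_segments, size=n_trials)
    pulse_sign = rng.choice([-1.0, 1.0], size=n_trials)  # congruent or incongruent
    seg_of_frame = np.repeat(np.arange(n_segments), per_seg)
    # pulse raises every frame of its segment by pulse_size; each other segment
    # is lowered by pulse_size/(n_segments-1), making the compensation exact at
    # the level of segment means.
    offset = np.where(
        seg_of_frame[None, :] == pulse_seg[:, None],
        pulse_size,
        -pulse_size / (n_segments - 1),
    )
    frames = frames + has_pulse[:, None] * pulse_sign[:, None] * offset

    mu_per_trial = np.full(n_trials, float(gen_mean_gap))
    if remove_mean:
        frames = frames - gen_mean_gap
        mu_per_trial = np.zeros(n_trials)
    return StimulusSet(
        frames=frames,
        frame_duration=frame_duration,
        mu_per_trial=mu_per_trial,
        sigma_s=float(frame_sd),
        kind="brightness_discs",
        seed=seed,
        coupling="drift",
        meta={
            "gen_mean_gap": gen_mean_gap,
            "pulse_prob": pulse_prob,
            "pulse_size": pulse_size,
            "n_segments": n_segments,
            "has_pulse": has_pulse,
            "pulse_segment": pulse_seg,
            "pulse_sign": pulse_sign,
            "removed_mean": remove_mean,
        },
    )


SINGLE_PULSE_COHERENCES = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)
TWO_PULSE_COHERENCES = (3.2, 6.4, 12.8)
TWO_PULSE_DELAYS_MS = (0, 120, 360, 1080)


def two_pulse_design(
    coherences=TWO_PULSE_COHERENCES,
    delays_ms=TWO_PULSE_DELAYS_MS,
    n_per_condition: int = 1000,
    single_coherences=SINGLE_PULSE_COHERENCES,
) -> pd.DataFrame:
    """Condition table of the two-pulse motion-discrimination design.

    Single-pulse conditions enumerate ``single_coherences`` (coh2 = NaN);
    two-pulse conditions cross every ordered coherence pair with every delay.
    Both pulses always share the motion direction (congruent design), so the
    table carries coherences only.
    """
    if any(c < 0 for c in coherences):
        raise ValueError("coherences must be non-negative")
    rows = [
        {"coh1": c, "coh2": np.nan, "delay_ms": np.nan, "n": n_per_condition}
        for c in single_coherences
    ]
    for c1 in coherences:
        for c2 in coherences:
            for d in delays_ms:
                rows.append({"coh1": c1, "coh2": c2, "delay_ms": d, "n": n_per_condition})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OUCurrents:
    """Paired Ornstein-Uhlenbeck stimulus currents for the two populations."""

    current_a: np.ndarray
    current_b: np.ndarray
    dt: float
    i0: float
    mu: float
    sigma_s: float
    tau_stim: float
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.current_a.shape[-1]) * self.dt


def ou_currents(
    mu: float,
    sigma_s: float,
    duration_s: float,
    dt_ms: float = 0.1,
    tau_stim_ms: float = 20.0,
    i0: float = 1.0,
    seed: int = 0,
    n_trials: int = 1,
    stream_index: int = 0,
) -> OUCurrents:
    """Stimulus currents I_A = I0(1+mu) + sigma_s z_A, I_B = I0(1-mu) + sigma_s z_B.

    z_A and z_B are independent unit-variance Ornstein-Uhlenbeck processes with
    correlation time ``tau_stim_ms`` (20 ms by default), advanced with the
    exact conditional-Gaussian update (not Euler), initialized from the
    stationary distribution.
    """
    if tau_stim_ms <= 0:
        raise ValueError("tau_stim must be positive")
    dt = dt_ms * 1e-3
    tau = tau_stim_ms * 1e-3
    n_steps = int(round(duration_s / dt))
    rng = rng_for(seed, "stimulus", stream_index)
    decay = np.exp(-dt / tau)
    innov_sd = np.sqrt(1.0 - decay**2)
    # z_t = decay * z_{t-1} + innov; an AR(1) recursion, run as an IIR filter
    from scipy.signal import lfilter

    z0 = rng.standard_normal((2, n_trials))  # stationary start
    eps = innov_sd * rng.standard_normal((2, n_trials, n_steps))
    eps[..., 0] = 0.0
    out = lfilter([1.0], [1.0, -decay], eps, axis=-1)
    out += z0[..., None] * decay ** np.arange(n_steps)
    out[..., 0] = z0
    return OUCurrents(
        current_a=i0 * (1.0 + mu) + sigma_s * out[0],
        current_b=i0 * (1.0 - mu) + sigma_s * out[1],
        dt=dt,
        i0=i0,
        mu=mu,
        sigma_s=sigma_s,
        tau_stim=tau,
        seed=seed,
    )
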