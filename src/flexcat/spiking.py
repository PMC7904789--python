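"""Reduced-scale winner-take-all spiking network.

Two populations of excitatory leaky integrate-and-fire neurons, each
selective for one choice, compete through a shared untuned inhibitory
population.  Connectivity is sparse and random (pairwise probability 0.1);
synapses are current-based with exponential decay and a fixed transmission
delay; every neuron additionally receives independent external Poisson input
through instantaneous synapses.  The stimulus is a pair of
Ornstein-Uhlenbeck currents (correlation time 20 ms) with means I0 (1 +/- mu)
and stationary sd sigma_S injected into the two excitatory populations.

Near the winner-take-all bifurcation the network realizes the same
double-well picture as the one-dimensional model: a symmetric low-rate state
destabilizes under stimulation into one of two asymmetric attractors, and
stimulus fluctuations can drive transitions between them.  The choice is the
population with the higher firing rate over the last 100 ms of the stimulus.

Voltages are in mV; currents are expressed as voltage equivalents I/g_L, so
the "pA" stimulus scale of a biophysical parameterization maps onto mV here.
Default sizes (200 + 200 excitatory, 100 inhibitory) are a five-fold reduced
scale with synaptic weights scaled up to preserve the mean recurrent drive;
weights and rates were tuned in-package for (a) a stable symmetric low state
without stimulus and (b) winner-take-all attractors under stimulation
(verified by the persistence check), since the biophysical values are not
fixed by the modeling literature this network abstracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from numba import njit

from ._rng import rng_for
from .stimuli import OUCurrents, ou_currents


class ConfigurationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetworkParams:
    """Structural, membrane, synaptic and stimulus parameters.

    All weights are postsynaptic-potential increments in mV; rates in Hz.
    """

    # sizes (reduced test scale; multiply by 5 for the full-scale network)
    n_e: int = 200
    n_i: int = 100
    conn_prob: float = 0.1
    # recurrent weights (mV per presynaptic spike, exponential synapses)
    j_ee: float = 0.8
    j_ie: float = 1.0
    j_ei: float = 2.0
    # external drive (instantaneous synapses)
    j_ext: float = 0.2
    ext_rate_e: float = 3900.0
    ext_rate_i: float = 4100.0
    # membrane
    tau_m_e: float = 0.020
    tau_m_i: float = 0.010
    e_l: float = 0.0
    theta: float = 20.0
    e_reset: float = 10.0
    t_ref: float = 0.002
    # synapses
    tau_s_e: float = 0.020
    tau_s_i: float = 0.010
    delay: float = 0.0005
    # stimulus
    i0: float = 3.0
    tau_stim: float = 0.020
    dt: float = 1e-4
    #: external Poisson drive handled exactly ("poisson") or in the standard
    #: diffusion limit ("diffusion", default: mean + white Gaussian of matched
    #: variance per step; much faster, indistinguishable at these rates)
    external_mode: str = "diffusion"

    def __post_init__(self) -> None:
        if not 0.0 <= self.conn_prob <= 1.0:
            raise ValueError("conn_prob must lie in [0, 1]")
        if self.external_mode not in ("poisson", "diffusion"):
            raise ValueError("external_mode must be 'poisson' or 'diffusion'")
        if self.theta <= self.e_reset:
            raise ValueError("threshold must exceed the reset potential")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown network parameters: {sorted(unknown)}")
        return cls(**data)


def full_scale(params: NetworkParams, factor: int = 5) -> NetworkParams:
    """Scale populations up by ``factor`` and weights down to preserve the
    mean recurrent drive."""
    return replace(
        params,
        n_e=params.n_e * factor,
        n_i=params.n_i * factor,
        j_ee=params.j_ee / factor,
        j_ie=params.j_ie / factor,
        j_ei=params.j_ei / factor,
    )


@dataclass
class Network:
    """A concrete network: parameters plus one connectivity realization."""

    params: NetworkParams
    w_aa: np.ndarray
    w_bb: np.ndarray
    w_ia: np.ndarray
    w_ib: np.ndarray
    w_ai: np.ndarray
    w_bi: np.ndarray
    connectivity_seed: int


@dataclass
class NetworkTrial:
    """Spike counts, rates and choice of one simulated trial."""

    counts_a: np.ndarray  # per-step population spike counts
    counts_b: np.ndarray
    counts_i: np.ndarray
    dt: float
    pre_steps: int
    choice: int  # +1 A, -1 B, 0 undecided (logged by the caller)
    n_e: int = 0
    n_i: int = 0
    stimulus: OUCurrents | None = None
    raster_a: np.ndarray | None = None  # (n_steps, n_e) uint8, opt-in
    raster_b: np.ndarray | None = None

    def population_rate(self, which: str = "a", window_s: float = 0.030) -> np.ndarray:
        """Instantaneous population rate (Hz per neuron, 30 ms count window)."""
        counts = {"a": self.counts_a, "b": self.counts_b, "i": self.counts_i}[which]
        n_neurons = self.n_i if which == "i" else self.n_e
        win = max(1, int(round(window_s / self.dt)))
        return np.convolve(counts, np.ones(win), mode="same") / (
            win * self.dt * max(n_neurons, 1)
        )

    def raster_events(self, which: str = "a") -> pd.DataFrame:
        """Spike events as a (time_s, neuron_id) table (requires opt-in raster)."""
        raster = {"a": self.raster_a, "b": self.raster_b}[which]
        if raster is None:
            raise ValueError("raster was not recorded; pass record_raster=True")
        step, neuron = np.nonzero(raster)
        return pd.DataFrame({"time_s": step * self.dt, "neuron_id": neuron})


def build_network(params: NetworkParams, seed: int = 0) -> Network:
    """Draw one sparse random connectivity realization.

    Weight matrices are dense (postsyn x presyn) with entry J on connected
    pairs; the two excitatory populations are coupled only through the
    inhibitory population.
    """
    rng = rng_for(seed, "connectivity")
    p = params.conn_prob

    def w(n_post, n_pre, j):
        return (rng.random((n_post, n_pre)) < p).astype(np.float64) * j

    return Network(
        params=params,
        w_aa=w(params.n_e, params.n_e, params.j_ee),
        w_bb=w(params.n_e, params.n_e, params.j_ee),
        w_ia=w(params.n_i, params.n_e, params.j_ie),
        w_ib=w(params.n_i, params.n_e, params.j_ie),
        w_ai=w(params.n_e, params.n_i, params.j_ei),
        w_bi=w(params.n_e, params.n_i, params.j_ei),
        connectivity_seed=seed,
    )


@njit(cache=True, fastmath=True)
def _lif_kernel(
    seed,
    n_steps,
    dt,
    v_a, v_b, v_i,
    w_aa, w_bb, w_ia, w_ib, w_ai, w_bi,
    tau_m_e, tau_m_i, e_l, theta, e_reset,
    decay_e, decay_i, delay_steps, ref_steps,
    lam_e, lam_i, j_ext, poisson_ext,
    stim_a, stim_b,
    counts_a, counts_b, counts_i,
    record_raster, raster_a, raster_b,
):  # pragma: no cover - exercised through run_trial
    np.random.seed(seed)
    _dummy = np.zeros(1)
    mean_e = j_ext * lam_e
    sd_e = j_ext * np.sqrt(lam_e)
    mean_i = j_ext * lam_i
    sd_i = j_ext * np.sqrt(lam_i)
    n_e = v_a.shape[0]
    n_i = v_i.shape[0]
    s_a_exc = np.zeros(n_e)
    s_a_inh = np.zeros(n_e)
    s_b_exc = np.zeros(n_e)
    s_b_inh = np.zeros(n_e)
    s_i_exc = np.zeros(n_i)
    ref_a = np.zeros(n_e, dtype=np.int64)
    ref_b = np.zeros(n_e, dtype=np.int64)
    ref_i = np.zeros(n_i, dtype=np.int64)
    buf_a = np.zeros((delay_steps, n_e), dtype=np.uint8)
    buf_b = np.zeros((delay_steps, n_e), dtype=np.uint8)
    buf_i = np.zeros((delay_steps, n_i), dtype=np.uint8)
    any_a = np.zeros(delay_steps, dtype=np.uint8)
    any_b = np.zeros(delay_steps, dtype=np.uint8)
    any_i = np.zeros(delay_steps, dtype=np.uint8)

    for t in range(n_steps):
        slot = t % delay_steps
        # deliver spikes emitted delay_steps ago (skip silent slots)
        if any_a[slot]:
            for j in range(n_e):
                if buf_a[slot, j]:
                    for i in range(n_e):
                        s_a_exc[i] += w_aa[i, j]
                    for i in range(n_i):
                        s_i_exc[i] += w_ia[i, j]
            buf_a[slot, :] = 0
            any_a[slot] = 0
        if any_b[slot]:
            for j in range(n_e):
                if buf_b[slot, j]:
                    for i in range(n_e):
                        s_b_exc[i] += w_bb[i, j]
                    for i in range(n_i):
                        s_i_exc[i] += w_ib[i, j]
            buf_b[slot, :] = 0
            any_b[slot] = 0
        if any_i[slot]:
            for j in range(n_i):
                if buf_i[slot, j]:
                    for i in range(n_e):
                        s_a_inh[i] += w_ai[i, j]
                        s_b_inh[i] += w_bi[i, j]
            buf_i[slot, :] = 0
            any_i[slot] = 0

        if not poisson_ext:
            eps_a = np.random.normal(0.0, 1.0, n_e)
            eps_b = np.random.normal(0.0, 1.0, n_e)
            eps_i = np.random.normal(0.0, 1.0, n_i)
        else:
            eps_a = _dummy
            eps_b = _dummy
            eps_i = _dummy
        ca = 0
        cb = 0
        ci = 0
        for i in range(n_e):
            if ref_a[i] > 0:
                ref_a[i] -= 1
                v_a[i] = e_reset
            else:
                v_a[i] += (dt / tau_m_e) * (
                    -(v_a[i] - e_l) + s_a_exc[i] - s_a_inh[i] + stim_a[t]
                )
                if poisson_ext:
                    v_a[i] += j_ext * np.random.poisson(lam_e)
                else:
                    v_a[i] += mean_e + sd_e * eps_a[i]
                if v_a[i] >= theta:
                    v_a[i] = e_reset
                    ref_a[i] = ref_steps
                    buf_a[slot, i] = 1
                    any_a[slot] = 1
                    ca += 1
                    if record_raster:
                        raster_a[t, i] = 1
            if ref_b[i] > 0:
                ref_b[i] -= 1
                v_b[i] = e_reset
            else:
                v_b[i] += (dt / tau_m_e) * (
                    -(v_b[i] - e_l) + s_b_exc[i] - s_b_inh[i] + stim_b[t]
                )
                if poisson_ext:
                    v_b[i] += j_ext * np.random.poisson(lam_e)
                else:
                    v_b[i] += mean_e + sd_e * eps_b[i]
                if v_b[i] >= theta:
                    v_b[i] = e_reset
                    ref_b[i] = ref_steps
                    buf_b[slot, i] = 1
                    any_b[slot] = 1
                    cb += 1
                    if record_raster:
                        raster_b[t, i] = 1
        for i in range(n_i):
            if ref_i[i] > 0:
                ref_i[i] -= 1
                v_i[i] = e_reset
            else:
                v_i[i] += (dt / tau_m_i) * (-(v_i[i] - e_l) + s_i_exc[i])
                if poisson_ext:
                    v_i[i] += j_ext * np.random.poisson(lam_i)
                else:
                    v_i[i] += mean_i + sd_i * eps_i[i]
                if v_i[i] >= theta:
                    v_i[i] = e_reset
                    ref_i[i] = ref_steps
                    buf_i[slot, i] = 1
                    any_i[slot] = 1
                    ci += 1
        counts_a[t] = ca
        counts_b[t] = cb
        counts_i[t] = ci

        for i in range(n_e):
            s_a_exc[i] *= decay_e
            s_b_exc[i] *= decay_e
            s_a_inh[i] *= decay_i
            s_b_inh[i] *= decay_i
        for i in range(n_i):
            s_i_exc[i] *= decay_e
        # (trace decay after use keeps the update order: deliver, integrate, decay)


def run_trial(
    network: Network,
    stimulus: OUCurrents | None,
    duration_s: float,
    pre_window_s: float = 0.5,
    seed: int = 0,
    record_raster: bool = False,
    extra_current_a: np.ndarray | None = None,
    extra_current_b: np.ndarray | None = None,
) -> NetworkTrial:
    """Simulate one trial: a 500 ms settling interval, then the stimulus.

    ``stimulus`` provides the paired OU currents for the stimulus period
    (trial 0 of the object is used); the choice is the excitatory population
    with more spikes over the last 100 ms of the stimulus.  A seeded coin
    breaks exact count ties; a trial silent in the readout window is
    undecided (choice 0).
    """
    p = network.params
    dt = p.dt
    pre_steps = int(round(pre_window_s / dt))
    stim_steps = int(round(duration_s / dt))
    n_steps = pre_steps + stim_steps

    stim_a = np.zeros(n_steps)
    stim_b = np.zeros(n_steps)
    if stimulus is not None:
        if stimulus.current_a.shape[-1] < stim_steps:
            raise ValueError("stimulus shorter than the trial's stimulus period")
        stim_a[pre_steps:] = stimulus.current_a[0, :stim_steps]
        stim_b[pre_steps:] = stimulus.current_b[0, :stim_steps]
    if extra_current_a is not None:
        stim_a += extra_current_a
    if extra_current_b is not None:
        stim_b += extra_current_b

    init_rng = rng_for(seed, "init")
    v_a = init_rng.uniform(p.e_reset, p.theta, size=p.n_e)
    v_b = init_rng.uniform(p.e_reset, p.theta, size=p.n_e)
    v_i = init_rng.uniform(p.e_reset, p.theta, size=p.n_i)

    counts_a = np.zeros(n_steps, dtype=np.int64)
    counts_b = np.zeros(n_steps, dtype=np.int64)
    counts_i = np.zeros(n_steps, dtype=np.int64)
    raster_shape = (n_steps, p.n_e) if record_raster else (1, 1)
    raster_a = np.zeros(raster_shape, dtype=np.uint8)
    raster_b = np.zeros(raster_shape, dtype=np.uint8)

    ext_seed = int(rng_for(seed, "external").integers(0, 2**31 - 1))
    _lif_kernel(
        ext_seed,
        n_steps,
        dt,
        v_a, v_b, v_i,
        network.w_aa, network.w_bb, network.w_ia, network.w_ib,
        network.w_ai, network.w_bi,
        p.tau_m_e, p.tau_m_i, p.e_l, p.theta, p.e_reset,
        np.exp(-dt / p.tau_s_e), np.exp(-dt / p.tau_s_i),
        max(1, int(round(p.delay / dt))), int(round(p.t_ref / dt)),
        p.ext_rate_e * dt, p.ext_rate_i * dt, p.j_ext,
        p.external_mode == "poisson",
        stim_a, stim_b,
        counts_a, counts_b, counts_i,
        record_raster, raster_a, raster_b,
    )

    readout = max(1, int(round(0.1 / dt)))
    n_a = int(counts_a[-readout:].sum())
    n_b = int(counts_b[-readout:].sum())
    if n_a == 0 and n_b == 0:
        choice = 0
    elif n_a == n_b:
        choice = 1 if rng_for(seed, "init", 1).random() < 0.5 else -1
    else:
        choice = 1 if n_a > n_b else -1
    return NetworkTrial(
        counts_a=counts_a,
        counts_b=counts_b,
        counts_i=counts_i,
        dt=dt,
        pre_steps=pre_steps,
        choice=choice,
        n_e=p.n_e,
        n_i=p.n_i,
        stimulus=stimulus,
        raster_a=raster_a if record_raster else None,
        raster_b=raster_b if record_raster else None,
    )


def check_attractor_persistence(
    params: NetworkParams,
    seed: int = 0,
    kick_mv: float = 4.0,
    kick_s: float = 0.3,
    hold_s: float = 1.0,
) -> dict:
    """Self-check of the winner-take-all regime.

    Runs one trial with the baseline stimulus I0 into both populations and a
    transient extra kick into population A; passes when A's rate stays well
    above B's for the full second after kick offset (attractor persistence)
    and when the pre-stimulus symmetric state shows no winner.
    """
    p = params
    duration = kick_s + hold_s
    stim = ou_currents(
        mu=0.0, sigma_s=0.0, duration_s=duration, dt_ms=p.dt * 1e3,
        i0=p.i0, seed=seed,
    )
    net = build_network(params, seed)
    pre_steps = int(round(0.5 / p.dt))
    extra = np.zeros(pre_steps + int(round(duration / p.dt)))
    extra[pre_steps : pre_steps + int(round(kick_s / p.dt))] = kick_mv
    trial = run_trial(net, stim, duration, seed=seed, extra_current_a=extra)

    hold_steps = int(round(hold_s / p.dt))
    rate_a = trial.counts_a[-hold_steps:].sum() / (p.n_e * hold_s)
    rate_b = trial.counts_b[-hold_steps:].sum() / (p.n_e * hold_s)
    pre = trial.counts_a[:pre_steps].sum(), trial.counts_b[:pre_steps].sum()
    pre_rate = (pre[0] + pre[1]) / (2 * p.n_e * 0.5)
    ok = rate_a > 3.0 * max(rate_b, 1e-9) and rate_a > 10.0 and pre_rate < rate_a / 2
    return {
        "ok": bool(ok),
        "rate_winner": float(rate_a),
        "rate_loser": float(rate_b),
        "rate_prestim": float(pre_rate),
    }


def require_winner_take_all(params: NetworkParams, seed: int = 0) -> None:
    check = check_attractor_persistence(params, seed)
    if not check["ok"]:
        raise ConfigurationError(
            "network is not in the winner-take-all regime "
            f"(winner {check['rate_winner']:.1f} Hz, loser {check['rate_loser']:.1f} Hz, "
            f"pre-stimulus {check['rate_prestim']:.1f} Hz); scale j_ee up or j_ei down"
        )


def run_experiment(
    params: NetworkParams,
    sigma_s_grid,
    T_grid,
    n_trials: int = 200,
    seed: int = 0,
    mu: float = 0.05,
    compute_kernels: bool = True,
    pk_bin_s: float = 0.1,
) -> dict:
    """Accuracy surface and psychophysical kernels over (sigma_S, T) cells.

    Every trial redraws the connectivity, the initial conditions, the
    external input and the stimulus (separate named streams).  Kernels are
    computed by reverse-correlating the choice against the injected
    current difference binned at ``pk_bin_s``; undecided trials are dropped
    (their count is reported).
    """
    from .kernels import compute_pk
    from .stimuli import StimulusSet

    sigma_s_grid = np.atleast_1d(np.asarray(sigma_s_grid, dtype=float))
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    rows = []
    kernels_out = {}
    cell = 0
    for T in T_grid:
        for sig in sigma_s_grid:
            cell += 1
            choices = np.zeros(n_trials, dtype=np.int8)
            n_bins = int(round(T / pk_bin_s))
            diffs = np.zeros((n_trials, n_bins))
            undecided = 0
            for trial_idx in range(n_trials):
                trial_seed = seed + 100_000 * cell + trial_idx
                stim = ou_currents(
                    mu=mu, sigma_s=sig, duration_s=T, dt_ms=params.dt * 1e3,
                    i0=params.i0, seed=trial_seed,
                )
                net = build_network(params, trial_seed)
                trial = run_trial(net, stim, T, seed=trial_seed)
                choices[trial_idx] = trial.choice
                if trial.choice == 0:
                    undecided += 1
                diff = stim.current_a[0] - stim.current_b[0]
                per_bin = int(round(pk_bin_s / params.dt))
                diffs[trial_idx] = diff[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
            decided = choices != 0
            acc = float(np.mean(choices[decided] == 1)) if decided.any() else np.nan
            n_dec = int(decided.sum())
            rows.append(
                {
                    "sigma_s": sig,
                    "T": T,
                    "mu": mu,
                    "n": n_trials,
                    "n_decided": n_dec,
                    "undecided": undecided,
                    "p_correct": acc,
                    "se": np.sqrt(acc * (1 - acc) / n_dec) if n_dec else np.nan,
                }
            )
            if compute_kernels and n_dec >= 8:
                stimset = StimulusSet(
                    frames=diffs[decided],
                    frame_duration=pk_bin_s,
                    mu_per_trial=diffs[decided].mean(axis=1),
                    sigma_s=sig,
                    kind="ou_current",
                    seed=seed,
                    coupling="drift",
                )
                kernels_out[(float(sig), float(T))] = compute_pk(
                    stimset, choices[decided]
                )
    return {"accuracy": pd.DataFrame(rows), "kernels": kernels_out}
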