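"""n-choice winner-take-all rate network.

Generalizes the beneficial-fluctuation effect beyond two choices: n
excitatory populations with self-excitation compete through one shared
inhibitory population,

    tau   dr_i/dt = -r_i + phi(s r_i - c r_I + I_i) + xi_i(t)
    tau_I dr_I/dt = -r_I + phi((g/n) sum_j r_j + I_I) + xi_I(t)

with the piecewise transfer phi(x) = 0 for x < 0, x^2 on [0, 1], and
2 sqrt(x - 3/4) above 1 (continuous and increasing).  Population 1 receives
the extra input (+ up-weighted share of Delta I); accuracy is the fraction
of trials in which r_1 has the highest rate at the end of the trial.  In the
winner-take-all regime, intermediate excitatory noise sigma allows
correcting transitions into the r_1-wins attractor, so accuracy can peak at
a non-zero noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import rng_for


def transfer(x):
    """Piecewise transfer function: 0, x^2, 2 sqrt(x - 3/4) (continuous)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mid = (x >= 0.0) & (x <= 1.0)
    out[mid] = x[mid] ** 2
    high = x > 1.0
    out[high] = 2.0 * np.sqrt(x[high] - 0.75)
    return out


@dataclass(frozen=True)
class RateNetParams:
    """Parameters of the n-choice rate network (defaults as used for n = 3)."""

    n_choices: int = 3
    s: float = 0.694
    c: float = field(default_factory=lambda: float(np.sqrt(5.0)))
    g: float = field(default_factory=lambda: float(np.sqrt(5.0)))
    tau: float = 0.020  # s
    tau_i: float = 0.010  # s
    i_mean: float = 2.25
    delta_i_scale: float = 0.03  # Delta I = 0.03 * s
    i_inh: float = 0.0
    sigma: float = 0.18  # excitatory noise amplitude
    sigma_i_pop: float = 0.0  # inhibitory noise amplitude

    def __post_init__(self) -> None:
        if self.n_choices not in (3, 4):
            raise ValueError("n_choices must be 3 or 4")

    @property
    def delta_i(self) -> float:
        return self.delta_i_scale * self.s

    def inputs(self) -> np.ndarray:
        """External inputs: population 1 gets I + (n-1) dI/n, others I - dI/n."""
        n, di = self.n_choices, self.delta_i
        ins = np.full(n, self.i_mean - di / n)
        ins[0] = self.i_mean + (n - 1) * di / n
        return ins


def simulate_ratenet(
    params: RateNetParams,
    duration_s: float = 2.0,
    n_trials: int = 1000,
    seed: int = 0,
    dt: float = 1e-4,
    favored: int = 0,
    return_rates: bool = False,
):
    """Euler integration of the rate equations; returns the accuracy.

    Accuracy is the fraction of trials in which the ``favored`` population
    (the one receiving +Delta I; index 0 by default, permuted on request to
    exercise label symmetry) has the maximal rate at exactly ``duration_s``.
    Rate ties are broken by a seeded coin.  Noise enters the rate update as
    sigma sqrt(dt/tau) per step.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    n = params.n_choices
    inputs = params.inputs()
    if favored != 0:
        perm = np.arange(n)
        perm[[0, favored]] = perm[[favored, 0]]
        inputs = inputs[perm]
    rng = rng_for(seed, "internal")
    r = np.zeros((n_trials, n))
    r_i = np.zeros(n_trials)
    n_steps = int(round(duration_s / dt))
    exc_noise = params.sigma * np.sqrt(dt / params.tau)
    inh_noise = params.sigma_i_pop * np.sqrt(dt / params.tau_i)
    for _ in range(n_steps):
        drive = transfer(params.s * r - params.c * r_i[:, None] + inputs[None, :])
        new_r = r + (dt / params.tau) * (-r + drive)
        if exc_noise > 0:
            new_r += exc_noise * rng.standard_normal((n_trials, n))
        inh_drive = transfer(params.g / n * r.sum(axis=1) + params.i_inh)
        r_i = r_i + (dt / params.tau_i) * (-r_i + inh_drive)
        if inh_noise > 0:
            r_i += inh_noise * rng.standard_normal(n_trials)
        r = new_r
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("rate blow-up: decrease the step size")
    winners = np.argmax(r, axis=1)
    # seeded tie-break on exact rate ties
    top = r[np.arange(n_trials), winners]
    tied = (r == top[:, None]).sum(axis=1) > 1
    for idx in np.nonzero(tied)[0]:
        cands = np.nonzero(r[idx] == top[idx])[0]
        winners[idx] = rng.choice(cands)
    acc = float(np.mean(winners == favored))
    if return_rates:
        return acc, r
    return acc


def accuracy_vs_noise(
    sigma_grid,
    params: RateNetParams | None = None,
    duration_s: float = 2.0,
    n_trials: int = 1000,
    seed: int = 0,
) -> dict:
    """Accuracy as a function of the excitatory noise amplitude."""
    params = params or RateNetParams()
    sigma_grid = np.atleast_1d(np.asarray(sigma_grid, dtype=float))
    acc = np.array(
        [
            simulate_ratenet(
                replace(params, sigma=s), duration_s, n_trials, seed + i
            )
            for i, s in enumerate(sigma_grid)
        ]
    )
    return {
        "sigma_grid": sigma_grid,
        "accuracy": acc,
        "se": np.sqrt(acc * (1 - acc) / n_trials),
        "n_trials": n_trials,
    }
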