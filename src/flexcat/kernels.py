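"""Psychophysical-kernel reverse correlation.

The psychophysical kernel (PK) measures when, during the stimulus, the
moment-by-moment fluctuations of the evidence influence the eventual choice.
For each time bin the per-trial fluctuation (frame value minus the trial's
generative mean) is split by the choice made, and the kernel value is the
area under the ROC curve separating the two conditional distributions,
computed rank-based (Mann-Whitney):

    PK(t) = P(fluct_R > fluct_L) + 0.5 * P(fluct_R = fluct_L)

A flat PK at 0.5 means no influence; primacy (recency) integration shows as
a decaying (rising) kernel.  Two normalized summary indices condense a
kernel:

* normalized area -- the trapezoidal integral of PK - 0.5 divided by that of
  a reference ideal observer (a perfect integrator without internal noise on
  the same stimulus ensemble); 1 means fluctuations are integrated as well as
  by the ideal observer, 0 means not at all.
* normalized slope -- the PK is first normalized to unit area, then fit with
  a line beta_0 + k*beta_1*t where k = 1/(2 var(t)); beta_1 lies in [-1, 1]
  with -1 pure primacy and +1 pure recency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._rng import rng_for
from .stimuli import StimulusSet

#: default reverse-correlation bin for sub-frame (integration-step) stimuli:
#: tau/10 with tau = 200 ms
DEFAULT_BIN_S = 0.02


class KernelError(ValueError):
    pass


@dataclass
class KernelResult:
    """Time-resolved AUROC kernel with optional summary indices and band."""

    pk: np.ndarray
    times: np.ndarray
    n_trials: int
    npka: float | None = None
    slope: float | None = None
    sem: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.pk.size


def _binned_fluctuations(stimuli: StimulusSet, bin_duration: float | None):
    """Average fluctuations within reverse-correlation bins."""
    fluct = stimuli.fluctuations()
    if bin_duration is None:
        bin_duration = (
            DEFAULT_BIN_S if stimuli.frame_duration < DEFAULT_BIN_S else stimuli.frame_duration
        )
    per_bin = bin_duration / stimuli.frame_duration
    if abs(per_bin - round(per_bin)) > 1e-9 or per_bin < 1:
        raise ValueError(
            f"bin duration {bin_duration} s is not an integer multiple of the "
            f"frame duration {stimuli.frame_duration} s"
        )
    per_bin = int(round(per_bin))
    n_bins = stimuli.n_frames // per_bin
    if n_bins < 1:
        raise ValueError("stimulus shorter than one reverse-correlation bin")
    fluct = fluct[:, : n_bins * per_bin].reshape(stimuli.n_trials, n_bins, per_bin).mean(axis=2)
    times = (np.arange(n_bins) + 0.5) * per_bin * stimuli.frame_duration
    return fluct, times


def _auroc(fluct: np.ndarray, choices: np.ndarray) -> np.ndarray:
    """Rank-based AUROC per column between rightward and leftward trials."""
    right = choices > 0
    n_r, n_l = int(right.sum()), int((~right).sum())
    ranks = rankdata(fluct, axis=0)
    rank_sum = ranks[right].sum(axis=0)
    return (rank_sum - n_r * (n_r + 1) / 2.0) / (n_r * n_l)


def compute_pk(
    stimuli: StimulusSet,
    choices: np.ndarray,
    bin_duration: float | None = None,
) -> KernelResult:
    """Reverse-correlate choices against stimulus fluctuations.

    The per-trial generative mean is removed before conditioning, so the two
    distributions are not trivially separated by the net evidence.  Requires
    at least two trials of each choice.
    """
    choices = np.asarray(choices)
    if choices.shape != (stimuli.n_trials,):
        raise ValueError("need one choice per trial")
    if (choices > 0).sum() < 2 or (choices < 0).sum() < 2:
        raise KernelError("kernel undefined: need at least two trials of each choice")
    fluct, times = _binned_fluctuations(stimuli, bin_duration)
    pk = _auroc(fluct, choices)
    result = KernelResult(pk=pk, times=times, n_trials=stimuli.n_trials)
    result.slope = pk_slope(result)
    return result


def npka(result: KernelResult, reference: KernelResult) -> float:
    """Kernel area normalized by an ideal-observer reference.

    ``reference`` must be the kernel of a perfect integrator without internal
    noise computed on the same stimulus ensemble (time grids must match).
    """
    if result.n_bins != reference.n_bins:
        raise ValueError("kernel and reference must share the time grid")
    num = np.trapezoid(result.pk - 0.5, result.times)
    den = np.trapezoid(reference.pk - 0.5, reference.times)
    if den <= 0:
        raise KernelError("reference kernel area is not positive")
    value = float(num / den)
    result.npka = value
    return value


def pk_slope(result: KernelResult) -> float:
    """Normalized slope in [-1, 1] of the unit-area kernel.

    The kernel is normalized to unit area, then least-squares fit with
    LPK(t) = beta_0 + k*beta_1*t, k = 1/(2 var(t)) with the population
    variance of the bin centers; beta_1 is returned.  A kernel with zero area
    has no defined shape and raises.
    """
    if result.n_bins < 2:
        raise KernelError("slope needs at least two time bins")
    t = result.times
    area = np.trapezoid(result.pk - 0.5, t)
    if area == 0:
        raise KernelError("slope undefined: kernel area is zero")
    npk = (result.pk - 0.5) / area
    var_t = t.var()
    ls_slope = np.polyfit(t, npk, 1)[0]
    # a kernel concentrated entirely at one end maps to -1/+1; kernels whose
    # early part dips below 0.5 can nominally overshoot and are clipped back
    # to the documented range
    return float(np.clip(ls_slope * 2.0 * var_t, -1.0, 1.0))


def pk_raw_slope(result: KernelResult) -> float:
    """Plain least-squares slope of PK(t) against time (AUROC units per s).

    The area-normalized slope divides by the kernel area, which is
    ill-conditioned when the area is near zero (e.g. network kernels whose
    early bins hover at 0.5); orderings across conditions are then better
    compared on this unnormalized slope.
    """
    if result.n_bins < 2:
        raise KernelError("slope needs at least two time bins")
    return float(np.polyfit(result.times, result.pk, 1)[0])


def bootstrap_pk(
    stimuli: StimulusSet,
    choices: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    bin_duration: float | None = None,
) -> KernelResult:
    """Kernel with a trial-resampling bootstrap band.

    Trials are resampled jointly (stimulus and choice together, preserving
    their dependence); the band is the per-bin standard deviation of the
    resampled kernels.  Resamples without both choices present are redrawn.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap repetitions")
    result = compute_pk(stimuli, choices, bin_duration)
    fluct, _ = _binned_fluctuations(stimuli, bin_duration)
    choices = np.asarray(choices)
    rng = rng_for(seed, "bootstrap")
    n = stimuli.n_trials
    boots = np.empty((n_boot, result.n_bins))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            c = choices[idx]
            if (c > 0).sum() >= 2 and (c < 0).sum() >= 2:
                break
        boots[b] = _auroc(fluct[idx], c)
    result.sem = boots.std(axis=0)
    return result
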