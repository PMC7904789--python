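"""Two-pulse working-memory analysis.

In the two-pulse motion task, subjects see one or two 120 ms pulses of
coherent motion (coherence sets {0, 3.2, 6.4, 12.8, 25.6, 51.2}% single,
{3.2, 6.4, 12.8}% x {3.2, 6.4, 12.8}% double, delays 0-1080 ms) and report
the common direction.  The double-well model solves both halves of the task:
the first pulse categorizes the evidence into an attractor, the attractor
stores it across the delay, and the second pulse can reverse an initially
wrong categorization far more easily than a correct one (the Kramers rate
asymmetry).

Closed-form accuracies chain the two-state theory through the pulses with
drift mu = k * coh:

    P^1 = P0 (1 - p_E) + (1 - P0) p_C            (single 120 ms pulse)
    P^2 = P^1 (1 - p_E') + (1 - P^1) p_C'        (second pulse, its own mu)

delay-independent by construction (delay transitions are bounded separately).
Parameters theta = (k, alpha, sigma, tau) are estimated by maximizing the
binomial log-likelihood sum_i [N_C,i log P_i + N_E,i log(1 - P_i)] with
Nelder-Mead restarts.  Because the fitted coherence scaling can push k*coh
beyond the double-well bifurcation at the highest coherences, the closed
forms use the O(mu) perturbative fixed points, which remain defined for all
mu.

The likelihood surface is a soft ridge: the delay-pooled accuracies pin the
first-visit geometry only through parameter combinations, and tau enters
only through the near-invisible within-pulse transition probabilities.  The
reported ``ci95`` are therefore profile likelihood-ratio intervals, which
stay calibrated along the ridge; the finite-difference Hessian (Wald)
intervals are kept in ``meta["ci95_wald"]``.

The primacy-recency index PRI = (beta_2 - beta_1)/(beta_1 + beta_2) comes
from a logistic regression of trial correctness on the two pulse coherences:
-1 is pure primacy, +1 pure recency.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numba import njit
from scipy.optimize import minimize
from scipy.special import erf
from scipy.stats import norm, qmc

from . import theory
from ._rng import rng_for
from .stimuli import (
    SINGLE_PULSE_COHERENCES,
    TWO_PULSE_COHERENCES,
    TWO_PULSE_DELAYS_MS,
    two_pulse_design,
)

PULSE_S = 0.120  # pulse duration of the task
MAX_DELAY_S = 1.080  # longest delay of the task, used for the noise bound

#: maximum-likelihood parameters reported for the pooled psychophysical data
FITTED_PARAMS = dict(k=0.012, alpha=0.70, sigma=0.52, tau_s=3.3)

DEFAULT_BOUNDS = {
    "k": (1e-4, 0.1),
    "alpha": (0.05, 3.0),
    "sigma": (0.05, 3.0),
    "tau_s": (0.2, 30.0),
}

PARAM_NAMES = ("k", "alpha", "sigma", "tau_s")


@dataclass(frozen=True)
class PulseParams:
    """Double-well parameters of the two-pulse task.

    ``k`` scales coherence (in %) to drift, mu = k * coh; ``sigma`` is the
    total noise sqrt(sigma_I^2 + sigma_S^2); ``tau_s`` the integration time
    constant in seconds.
    """

    k: float
    alpha: float
    sigma: float
    tau_s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.k, self.alpha, self.sigma, self.tau_s])

    @classmethod
    def from_array(cls, x) -> "PulseParams":
        return cls(*(float(v) for v in x))


@dataclass
class PulseFitResult:
    params: PulseParams
    ci95: dict
    loglik: float
    predictions: pd.DataFrame
    sigma_i_max: float
    pri: float | None = None
    n_restarts: int = 0
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "params": {n: getattr(self.params, n) for n in PARAM_NAMES},
            "ci95": self.ci95,
            "loglik": self.loglik,
            "sigma_i_max": self.sigma_i_max,
            "pri": self.pri,
            "converged": self.converged,
            "predictions": self.predictions.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# closed-form condition accuracies (vectorized over coherences)
# ---------------------------------------------------------------------------

def _geometry(mu, alpha, sigma):
    """Perturbative fixed points, P0 (erf form), and Kramers rates.

    All quantities are numpy-vectorized over ``mu``; the O(mu) fixed points
    x_att = +/- sqrt(alpha/2) + mu/(4 alpha), x_U = -mu/(2 alpha) stay
    defined for every tilt the optimizer explores (the exact cubic roots
    cease to exist beyond the bifurcation at the highest coherences).
    """
    mu = np.asarray(mu, dtype=float)
    a = np.sqrt(alpha / 2.0)
    x_c = a + mu / (4.0 * alpha)
    x_e = -a + mu / (4.0 * alpha)
    x_u = -mu / (2.0 * alpha)

    def phi(x):
        return -mu * x - alpha * x**2 + x**4

    def curv(x):
        return -2.0 * alpha + 12.0 * x**2

    s2 = sigma**2
    u = lambda x: (np.sqrt(2.0 * alpha) / sigma) * (x + mu / (2.0 * alpha))
    num = erf(u(np.zeros_like(mu))) - erf(u(x_e))
    den = erf(u(x_c)) - erf(u(x_e))
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.clip(num / den, 0.0, 1.0)
    # both erfs saturated: strong tilt resolves the start deterministically
    p0 = np.where((den <= 0) | ~np.isfinite(p0),
                  np.where(mu > 0, 1.0, np.where(mu < 0, 0.0, 0.5)), p0)

    pref_c = np.sqrt(np.abs(curv(x_e) * curv(x_u))) / (2.0 * np.pi)
    pref_e = np.sqrt(np.abs(curv(x_c) * curv(x_u))) / (2.0 * np.pi)
    phi_u = phi(x_u)
    k_c = pref_c * np.exp(np.clip(-2.0 * (phi_u - phi(x_e)) / s2, -745.0, 50.0))
    k_e = pref_e * np.exp(np.clip(-2.0 * (phi_u - phi(x_c)) / s2, -745.0, 50.0))
    return p0, k_c, k_e


def _chain(p_in, mu, params: PulseParams):
    """Advance the two-state occupancy through one 120 ms pulse of tilt mu."""
    _, k_c, k_e = _geometry(mu, params.alpha, params.sigma)
    k = k_c + k_e
    with np.errstate(divide="ignore", invalid="ignore"):
        p_inf = np.where(k > 0, k_c / np.where(k > 0, k, 1.0), 0.5)
    activation = -np.expm1(-k * PULSE_S / params.tau_s)
    p_c = p_inf * activation
    p_e = (1.0 - p_inf) * activation
    return p_in * (1.0 - p_e) + (1.0 - p_in) * p_c


def _pulse_step(p_correct_in: float, coh: float, params: PulseParams) -> float:
    """Scalar convenience wrapper around :func:`_chain`."""
    return float(_chain(np.asarray(p_correct_in, dtype=float),
                        params.k * float(coh), params))


def predict_single(coh, params: PulseParams) -> float | np.ndarray:
    """Accuracy after a single 120 ms pulse at coherence ``coh`` (percent)."""
    scalars = np.isscalar(coh)
    mu = params.k * np.atleast_1d(coh).astype(float)
    p0, _, _ = _geometry(mu, params.alpha, params.sigma)
    out = _chain(p0, mu, params)
    return float(out[0]) if scalars else out


def predict_double(coh1, coh2, params: PulseParams) -> float | np.ndarray:
    """Accuracy after two congruent 120 ms pulses, delay-independent."""
    scalars = np.isscalar(coh1) and np.isscalar(coh2)
    c1 = np.atleast_1d(coh1).astype(float)
    c2 = np.atleast_1d(coh2).astype(float)
    if c1.shape != c2.shape:
        raise ValueError("coh1 and coh2 must align")
    p1 = predict_single(c1, params)
    out = _chain(np.atleast_1d(p1), params.k * c2, params)
    return float(out[0]) if scalars else out


def predict_table(table: pd.DataFrame, params: PulseParams) -> np.ndarray:
    """Predicted accuracy for each row of a condition table."""
    c1 = table["coh1"].to_numpy(dtype=float)
    c2 = table["coh2"].to_numpy(dtype=float)
    singles = np.isnan(c2)
    preds = np.empty(len(table))
    if singles.any():
        preds[singles] = np.atleast_1d(predict_single(c1[singles], params))
    if (~singles).any():
        preds[~singles] = np.atleast_1d(
            predict_double(c1[~singles], c2[~singles], params)
        )
    return preds


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def pool_delays(table: pd.DataFrame) -> pd.DataFrame:
    """Pool trial counts across delays per coherence sequence (the model's
    predicted accuracies are delay-independent)."""
    key = table.assign(coh2=table["coh2"].fillna(-1.0))
    grouped = (
        key.groupby(["coh1", "coh2"], as_index=False)[["n_trials", "n_correct"]].sum()
    )
    grouped["coh2"] = grouped["coh2"].replace(-1.0, np.nan)
    return grouped


def log_likelihood(
    table: pd.DataFrame, params: PulseParams, printed_form: bool = False
) -> float:
    """Binomial log-likelihood of a pooled condition table.

    ``printed_form=True`` evaluates sum N_C P + N_E (1 - P) instead -- kept
    for archaeology only; it is not a likelihood and its optimum saturates at
    P in {0, 1}.
    """
    p = np.clip(predict_table(table, params), 1e-9, 1 - 1e-9)
    n_c = table["n_correct"].to_numpy(dtype=float)
    n_e = table["n_trials"].to_numpy(dtype=float) - n_c
    if printed_form:
        return float(np.sum(n_c * p + n_e * (1.0 - p)))
    return float(np.sum(n_c * np.log(p) + n_e * np.log1p(-p)))


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                hess[i, j] = hess[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess


class FitError(RuntimeError):
    pass


@njit(cache=True)
def _nll_compiled(x, lo, hi, c1, c2, is_single, n_c, n_e):
    """Compiled negative binomial log-likelihood of a pooled table.

    Scalar re-implementation of the `_geometry`/`_chain` closed forms; the
    simplex and the profile walks call this tens of thousands of times.
    ``is_single`` marks single-pulse rows; out-of-bounds points return a
    smooth penalty wall.
    """
    overshoot = 0.0
    for i in range(4):
        if x[i] < lo[i]:
            overshoot += lo[i] - x[i]
        elif x[i] > hi[i]:
            overshoot += x[i] - hi[i]
    if overshoot > 0.0:
        return 1e8 * (1.0 + overshoot)
    k, alpha, sigma, tau_s = x[0], x[1], x[2], x[3]
    a = np.sqrt(alpha / 2.0)
    s2 = sigma * sigma
    pref = np.sqrt(2.0 * alpha) / sigma
    total = 0.0
    for i in range(c1.shape[0]):
        p = -1.0
        for pulse in range(2):
            if pulse == 0:
                mu = k * c1[i]
            else:
                if is_single[i]:  # single-pulse condition: one pulse only
                    break
                mu = k * c2[i]
            shift = mu / (2.0 * alpha)
            x_c = a + mu / (4.0 * alpha)
            x_e = -a + mu / (4.0 * alpha)
            x_u = -mu / (2.0 * alpha)
            # P0 by quadratic completion (erf closed form)
            if pulse == 0:
                num = math.erf(pref * shift) - math.erf(pref * (x_e + shift))
                den = math.erf(pref * (x_c + shift)) - math.erf(pref * (x_e + shift))
                if den <= 0.0 or not np.isfinite(den):
                    p = 1.0 if mu > 0 else (0.0 if mu < 0 else 0.5)
                else:
                    p = num / den
                    if p < 0.0:
                        p = 0.0
                    elif p > 1.0:
                        p = 1.0
            # Kramers rates with the perturbative fixed points
            curv_u = abs(-2.0 * alpha + 12.0 * x_u * x_u)
            curv_e = abs(-2.0 * alpha + 12.0 * x_e * x_e)
            curv_c = abs(-2.0 * alpha + 12.0 * x_c * x_c)
            phi_u = -mu * x_u - alpha * x_u * x_u + x_u**4
            phi_e = -mu * x_e - alpha * x_e * x_e + x_e**4
            phi_c = -mu * x_c - alpha * x_c * x_c + x_c**4
            arg_c = -2.0 * (phi_u - phi_e) / s2
            arg_e = -2.0 * (phi_u - phi_c) / s2
            arg_c = min(max(arg_c, -745.0), 50.0)
            arg_e = min(max(arg_e, -745.0), 50.0)
            k_c = np.sqrt(curv_e * curv_u) / (2.0 * np.pi) * np.exp(arg_c)
            k_e = np.sqrt(curv_c * curv_u) / (2.0 * np.pi) * np.exp(arg_e)
            ktot = k_c + k_e
            p_inf = k_c / ktot if ktot > 0 else 0.5
            activation = -np.expm1(-ktot * PULSE_S / tau_s)
            p = p * (1.0 - (1.0 - p_inf) * activation) + (1.0 - p) * p_inf * activation
        if p < 1e-9:
            p = 1e-9
        elif p > 1.0 - 1e-9:
            p = 1.0 - 1e-9
        total += n_c[i] * np.log(p) + n_e[i] * np.log1p(-p)
    return -total


#: half the 95% chi-square quantile with one degree of freedom
_LR_DROP = 1.9207


def _profile_ci(neg_ll, x_hat: np.ndarray, f_hat: float, lo: np.ndarray,
                hi: np.ndarray, step0: np.ndarray | None = None,
                atlas: list | None = None, n_steps: int = 12) -> dict:
    """Profile likelihood-ratio 95% intervals per parameter.

    For each parameter the endpoint is where the negative log-likelihood
    minimized over the remaining parameters rises chi2_{0.95,1}/2 above the
    optimum.  The profile is traced by small-step continuation outward from
    the optimum (the surface is a curved ridge: large steps lose the path of
    the nuisance minimizers and overstate the drop), warm-starting each
    nuisance search from its neighbor with the optimum's nuisances as a
    fallback.  An apparent crossing is verified by probing one grid point
    further with the other restart optima (``atlas``) as extra starts: a
    profile that dips back below the threshold there was a false barrier
    (a branch switch the continuation missed) and the walk resumes.  The
    crossing is linearly interpolated; an endpoint that reaches its bound
    reports the distance to the bound.  The reported half-width is the
    larger of the two sides.
    """
    target = f_hat + _LR_DROP

    def profiled(j, value, warm, extra=()):
        keep = [i for i in range(x_hat.size) if i != j]

        def inner(z):
            full = np.empty(x_hat.size)
            full[keep] = z
            full[j] = value
            return neg_ll(full)

        starts = [warm[keep], x_hat[keep]] + [np.asarray(e)[keep] for e in extra]
        best_fun, best_x = np.inf, None
        for z0 in starts:
            res = minimize(inner, z0, method="Nelder-Mead",
                           options={"maxiter": 250, "xatol": 1e-6, "fatol": 1e-8})
            if res.fun < best_fun:
                best_fun, best_x = res.fun, res.x
        full = np.empty(x_hat.size)
        full[keep] = best_x
        full[j] = value
        if best_fun < found["fun"]:
            found["fun"], found["x"] = best_fun, full.copy()
        return best_fun, full

    found = {"fun": f_hat, "x": x_hat.copy()}
    atlas = list(atlas or [])
    # deterministic global fallbacks for branch switches the restarts missed
    atlas.append(lo + 0.3 * (hi - lo))
    atlas.append(lo + 0.7 * (hi - lo))
    ci = {}
    for j, name in enumerate(PARAM_NAMES):
        halves = []
        for direction in (+1.0, -1.0):
            bound = hi[j] if direction > 0 else lo[j]
            span = abs(bound - x_hat[j])
            if span <= 0:
                halves.append(0.0)
                continue
            grid = x_hat[j] + direction * span * (np.arange(1, n_steps + 1) / n_steps)
            warm = x_hat.copy()
            values = np.empty(n_steps)
            for i, v in enumerate(grid):
                f_v, warm = profiled(j, v, warm)
                if f_v >= target:
                    # suspicious rise: retry with the branch atlas and the
                    # global fallback starts before trusting it
                    f_retry, warm_retry = profiled(j, v, warm, extra=atlas)
                    if f_retry < f_v:
                        f_v, warm = f_retry, warm_retry
                values[i] = f_v
            # hull of the sub-threshold set: the profile can dip back below
            # the threshold past an apparent barrier (branch structure), so
            # the interval extends to the furthest sub-threshold point
            below = np.nonzero(values < target)[0]
            if below.size == n_steps or (below.size and below[-1] == n_steps - 1):
                half = span
            elif below.size == 0:
                frac = (target - f_hat) / max(values[0] - f_hat, 1e-12)
                half = frac * abs(grid[0] - x_hat[j])
            else:
                i_last = below[-1]
                t_in = abs(grid[i_last] - x_hat[j])
                t_out = abs(grid[i_last + 1] - x_hat[j])
                frac = (target - values[i_last]) / max(
                    values[i_last + 1] - values[i_last], 1e-12
                )
                half = t_in + frac * (t_out - t_in)
            halves.append(half)
        ci[name] = float(max(halves))
    return ci, found


def fit(
    table: pd.DataFrame,
    init: PulseParams | None = None,
    bounds: dict | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    do_pool_delays: bool = True,
    compute_pri: bool = False,
) -> PulseFitResult:
    """Maximum-likelihood fit of (k, alpha, sigma, tau) to a condition table.

    ``table`` needs columns coh1, coh2 (NaN for single pulses), n_trials,
    n_correct.  Nelder-Mead is restarted from ``init`` (if given) plus
    Latin-hypercube points within ``bounds``; the best log-likelihood wins.
    ``ci95`` are profile likelihood-ratio intervals (see module docstring);
    Wald/Hessian intervals are reported in ``meta["ci95_wald"]``.
    """
    table = table.copy()
    if "n_trials" not in table and "n" in table:
        table = table.rename(columns={"n": "n_trials"})
    required = {"coh1", "coh2", "n_trials", "n_correct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["n_correct"] > table["n_trials"]).any():
        raise ValueError("n_correct cannot exceed n_trials")
    if do_pool_delays:
        table = pool_delays(table)
    informative = table["coh1"].gt(0) | table["coh2"].fillna(0).gt(0)
    if int(informative.sum()) < 4:
        raise ValueError("need at least 4 informative conditions")

    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([bounds[n][1] for n in PARAM_NAMES])

    # hoist the table out of pandas once; the objective is called tens of
    # thousands of times across restarts and profile intervals
    c1 = table["coh1"].to_numpy(dtype=float)
    c2 = table["coh2"].to_numpy(dtype=float)
    singles = np.isnan(c2)
    n_c = table["n_correct"].to_numpy(dtype=float)
    n_e = table["n_trials"].to_numpy(dtype=float) - n_c

    c2_filled = np.where(singles, 0.0, c2)

    def neg_ll(x: np.ndarray) -> float:
        return _nll_compiled(
            np.asarray(x, dtype=float), lo, hi, c1, c2_filled,
            singles, n_c, n_e,
        )

    rng = rng_for(seed, "fit")
    sampler = qmc.LatinHypercube(d=4, rng=rng)
    starts = [qmc.scale(sampler.random(1), lo, hi)[0] for _ in range(n_restarts)]
    if init is not None:
        starts.insert(0, init.as_array())

    best = None
    finishers = []  # distinct restart optima: a map of the likelihood branches
    for x0 in starts:
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        if res.fun < 1e7:
            finishers.append((res.fun, res.x.copy()))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e8:
        raise FitError(f"no restart converged inside the bounds; trace: {best}")
    # polish: restart the simplex at the winner (fresh simplex scale) until
    # the improvement stalls, so the intervals sit at a genuine optimum
    for _ in range(3):
        res = minimize(
            neg_ll, best.x, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11},
        )
        if res.fun >= best.fun - 1e-10:
            best = res if res.fun < best.fun else best
            break
        best = res

    # interval estimation; the profile walk doubles as a global-search
    # diagnostic -- when it uncovers a better optimum (a branch the restarts
    # missed), the fit is re-polished there and the intervals recomputed
    for _round in range(3):
        x_hat = best.x
        # Wald intervals from the finite-difference observed information, the
        # information projected onto its positive cone (the surface has a
        # soft ridge: tau is weakly identified from delay-pooled accuracies)
        hess = _numerical_hessian(neg_ll, x_hat)
        eigval, eigvec = np.linalg.eigh((hess + hess.T) / 2.0)
        floor = max(abs(eigval).max(), 1.0) * 1e-10
        cov = (eigvec / np.maximum(eigval, floor)) @ eigvec.T
        ci_wald = {
            n: float(1.96 * np.sqrt(v)) if v > 0 else float("nan")
            for n, v in zip(PARAM_NAMES, np.diag(cov))
        }
        # reported ci95: profile likelihood-ratio intervals (Wald
        # extrapolates badly along the ridge and under-covers there)
        wald_scale = np.array([
            ci_wald[n] / 1.96 if np.isfinite(ci_wald[n]) else (hi[j] - lo[j]) / 4.0
            for j, n in enumerate(PARAM_NAMES)
        ])
        # distinct restart optima within a plausible likelihood distance act
        # as extra inner starts when profiling (branch atlas)
        scale = np.maximum(np.abs(x_hat), 1e-3)
        atlas = []
        for fun, x in sorted(finishers, key=lambda t: t[0]):
            if fun > best.fun + 50.0:
                continue
            if all(np.max(np.abs(x - a) / scale) > 0.05 for a in atlas + [x_hat]):
                atlas.append(x)
            if len(atlas) >= 3:
                break
        ci, found = _profile_ci(neg_ll, x_hat, best.fun, lo, hi,
                                step0=wald_scale, atlas=atlas)
        if found["fun"] >= best.fun - 1e-6:
            break
        res = minimize(
            neg_ll, found["x"], method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11},
        )
        finishers.append((res.fun, res.x.copy()))
        if res.fun > found["fun"]:  # polishing should not lose ground
            res.x, res.fun = found["x"], found["fun"]
        best = res

    x_hat = best.x
    params = PulseParams.from_array(x_hat)
    preds = predict_table(table, params)
    if np.any(preds <= 1e-9) or np.any(preds >= 1 - 1e-9):
        warnings.warn("predicted accuracies clipped at the 0/1 boundary", RuntimeWarning)

    out_table = table.copy()
    out_table["p_model"] = preds
    out_table["p_observed"] = out_table["n_correct"] / out_table["n_trials"]
    result = PulseFitResult(
        params=params,
        ci95=ci,
        loglik=-best.fun,
        predictions=out_table,
        sigma_i_max=theory.max_internal_noise(params.alpha, params.tau_s, MAX_DELAY_S),
        n_restarts=len(starts),
        converged=bool(best.success),
        meta={"optimizer": "Nelder-Mead", "bounds": bounds,
              "ci95_wald": ci_wald},
    )
    if compute_pri:
        result.pri = model_pri(params, seed=seed)
    return result


# ---------------------------------------------------------------------------
# synthetic tables and trial-level simulation
# ---------------------------------------------------------------------------

def simulate_condition_table(
    params: PulseParams,
    n_per_condition: int = 10_000,
    seed: int = 0,
    design: pd.DataFrame | None = None,
    do_pool_delays: bool = True,
) -> pd.DataFrame:
    """Binomial condition table drawn from the model's predicted accuracies.

    The default design enumerates the task's single-pulse coherences and the
    nine two-pulse sequences crossed with the four delays; with
    ``do_pool_delays`` the delayed replicates are pooled per sequence, as the
    fit assumes.
    """
    if design is None:
        design = two_pulse_design(n_per_condition=n_per_condition)
    design = design.rename(columns={"n": "n_trials"})
    rng = rng_for(seed, "stimulus")
    p = predict_table(design, params)
    n = design["n_trials"].to_numpy(dtype=int)
    design = design.assign(n_correct=rng.binomial(n, p))
    if do_pool_delays:
        design = pool_delays(design)
    return design


def simulate_trials(
    params: PulseParams,
    n_per_condition: int = 1000,
    seed: int = 0,
    coherences=TWO_PULSE_COHERENCES,
) -> pd.DataFrame:
    """Trial-level two-pulse outcomes (coh1, coh2, correct) from the model."""
    rng = rng_for(seed, "stimulus")
    rows = []
    for c1 in coherences:
        for c2 in coherences:
            p = predict_double(c1, c2, params)
            correct = rng.random(n_per_condition) < p
            rows.append(
                pd.DataFrame({"coh1": c1, "coh2": c2, "correct": correct.astype(int)})
            )
    return pd.concat(rows, ignore_index=True)


def pri(trials: pd.DataFrame) -> float:
    """Primacy-recency index from trial-level two-pulse data.

    Logistic regression logit P(correct) = b0 + b1 coh1 + b2 coh2, then
    PRI = (b2 - b1)/(b1 + b2).  Separation triggers an L2-regularized refit
    (with a warning).
    """
    if trials["coh1"].nunique() < 2 or trials["coh2"].nunique() < 2:
        raise ValueError("both pulse coherences must vary across trials")
    X = sm.add_constant(trials[["coh1", "coh2"]].to_numpy(dtype=float))
    y = trials["correct"].to_numpy(dtype=float)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = model.fit(disp=0)
        beta = res.params
    except Exception:
        warnings.warn("separation in logistic fit; refitting with L2 penalty",
                      RuntimeWarning)
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
        beta = np.asarray(res.params)
    b1, b2 = float(beta[1]), float(beta[2])
    return (b2 - b1) / (b1 + b2)


def model_pri(
    params: PulseParams, n_per_condition: int = 20_000, seed: int = 0
) -> float:
    """PRI of the fitted model, from simulated trial-level outcomes."""
    return pri(simulate_trials(params, n_per_condition, seed))


# ---------------------------------------------------------------------------
# delay robustness
# ---------------------------------------------------------------------------

PI_DRIFT_SCALE = 0.44  # mu_PI = 0.44 * k * coh for the perfect-integrator twin


def pi_double_pulse_accuracy(
    coh1: float, coh2: float, params: PulseParams, delay_s: float,
    sigma_i: float,
) -> float:
    """Perfect-integrator accuracy for two pulses separated by a delay.

    The accumulated evidence after both pulses is Gaussian with mean
    (mu1 + mu2) T_p / tau (mu = 0.44 k coh) and variance
    (2 T_p sigma^2 + T_delay sigma_I^2) / tau -- the total noise diffuses
    during the pulses, the internal noise alone during the delay -- giving
    P = Phi(mu_tot T_p / sqrt(tau (2 T_p sigma^2 + T_delay sigma_I^2))).
    """
    mu_tot = PI_DRIFT_SCALE * params.k * (coh1 + coh2)
    tau = params.tau_s
    var = tau * (params.sigma**2 * 2.0 * PULSE_S + sigma_i**2 * delay_s)
    if var <= 0:
        return 1.0 if mu_tot > 0 else 0.5
    return float(norm.cdf(mu_tot * PULSE_S / np.sqrt(var)))


def dwm_delay_accuracy(
    coh1: float, coh2: float, params: PulseParams, delay_s: float, sigma_i: float
) -> float:
    """Double-well accuracy for two pulses with delay switches included.

    During the delay the tilt is zero and only internal noise acts; the
    stored state flips with the symmetric two-state probability, after which
    the second pulse is chained as usual.
    """
    p1 = predict_single(coh1, params)
    p_d = theory.delay_switch_probability(params.alpha, sigma_i, params.tau_s, delay_s)
    p_after = p1 * (1.0 - p_d) + (1.0 - p1) * p_d
    return _pulse_step(p_after, coh2, params)


def delay_robustness(
    params: PulseParams,
    delays_s=None,
    threshold: float = 0.01,
    coh: float = 6.4,
    sigma_i: float | None = None,
) -> dict:
    """Delay-compatibility bound and accuracy-versus-delay curves.

    ``sigma_i_max`` is the internal noise at which the analytic switch
    probability over the longest (1.08 s) delay reaches ``threshold``; below
    it the double-well accuracy is delay-independent.  The curves compare the
    double well with a perfect integrator whose stored evidence diffuses
    under the same internal noise throughout the delay.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    delays_s = np.linspace(0.0, MAX_DELAY_S, 10) if delays_s is None else np.asarray(
        delays_s, dtype=float
    )
    sigma_i_max = theory.max_internal_noise(
        params.alpha, params.tau_s, MAX_DELAY_S, threshold
    )
    s_i = sigma_i_max if sigma_i is None else sigma_i
    dwm = np.array([dwm_delay_accuracy(coh, coh, params, d, s_i) for d in delays_s])
    pi_curve = np.array(
        [pi_double_pulse_accuracy(coh, coh, params, d, s_i) for d in delays_s]
    )
    return {
        "sigma_i_max": sigma_i_max,
        "delays_s": delays_s,
        "dwm_accuracy": dwm,
        "pi_accuracy": pi_curve,
        "sigma_i": s_i,
    }
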