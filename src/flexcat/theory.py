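"""Analytic accuracy of the double-well model via Kramers rate theory.

Provided the barrier between the two attractors is large compared with the
total noise variance sigma^2 = sigma_I^2 + sigma_S^2, the diffusion reduces
to a two-state Markov chain between the correct and the error attractor.
The chain is assembled from:

* P0 -- the probability of first visiting the correct attractor, the
  splitting probability of the diffusion started at x0.  The default is the
  closed erf form obtained by neglecting the quartic term near the barrier
  top; exact quadrature of the splitting integrals is available as a mode.
* k_C, k_E -- Kramers escape rates out of the error / correct attractor,
  with curvature prefactor sqrt(|phi''(x_att) phi''(x_U)|)/(2 pi) and
  exponent -2*(barrier)/sigma^2.  The rates are per unit dimensionless time
  t/tau (the natural clock of tau dx/dt = -phi' + sigma xi); divide by tau
  for per-second rates.
* p_C(T), p_E(T) -- the per-trial transition probabilities
  p_C = P_inf (1 - exp(-kT)), p_E = (1 - P_inf)(1 - exp(-kT)) with
  k = k_C + k_E and stationary accuracy P_inf = k_C/k.

The trial accuracy is P = P0 (1 - p_E) + (1 - P0) p_C, algebraically equal
to P0 exp(-kT) + P_inf (1 - exp(-kT)); both forms are evaluated and checked
against each other.  The same symmetric chain at mu = 0 gives the
probability of a memory-delay switch, used to bound the internal noise
compatible with delay-independent accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf

from .potentials import PotentialSpec, SingleWellError, double_well, mu_critical


@dataclass(frozen=True)
class KramersPrediction:
    """Two-state theory summary for one (potential, sigma, T) point.

    Rates are per unit t/tau; ``accuracy`` is the trial accuracy P.
    """

    p0: float
    k_c: float
    k_e: float
    p_c: float
    p_e: float
    p_inf: float
    accuracy: float
    fixed_points: tuple[float, float, float]
    sigma: float
    T_over_tau: float

    def as_dict(self) -> dict:
        return {
            "p0": self.p0,
            "k_c": self.k_c,
            "k_e": self.k_e,
            "p_c": self.p_c,
            "p_e": self.p_e,
            "p_inf": self.p_inf,
            "accuracy": self.accuracy,
            "x_e": self.fixed_points[0],
            "x_u": self.fixed_points[1],
            "x_c": self.fixed_points[2],
            "sigma": self.sigma,
            "T_over_tau": self.T_over_tau,
        }


def fixed_points(potential: PotentialSpec, method: str = "exact"):
    """(x_E, x_U, x_C), sorted; see :meth:`PotentialSpec.fixed_points`."""
    return potential.fixed_points(method)


def first_visit_probability(
    potential: PotentialSpec,
    sigma_total: float,
    x0: float = 0.0,
    method: str = "erf",
    fp_method: str = "exact",
) -> float:
    """Probability P0 of reaching the correct attractor before the error one.

    ``method="erf"`` uses the closed form with the quartic term neglected
    around the barrier top (the quadratic completion of -mu x - alpha x^2);
    ``method="quadrature"`` integrates exp(2 phi / sigma^2) numerically.
    """
    if sigma_total <= 0:
        raise ValueError("sigma_total must be positive")
    x_e, _, x_c = potential.fixed_points(fp_method)
    if method == "erf":
        a, mu = potential.alpha, potential.mu
        u = lambda x: (np.sqrt(2.0 * a) / sigma_total) * (x + mu / (2.0 * a))
        num = erf(u(x0)) - erf(u(x_e))
        den = erf(u(x_c)) - erf(u(x_e))
        if den <= 0 or not np.isfinite(den):
            # both erfs saturated: the splitting weight piles up at one edge
            # (very strong tilt relative to the noise); the start point then
            # deterministically resolves with the tilt
            return 1.0 if mu > 0 else (0.0 if mu < 0 else 0.5)
        return float(min(max(num / den, 0.0), 1.0))
    if method == "quadrature":
        s2 = sigma_total**2
        phi0 = float(potential.potential(0.0))  # stabilize the exponentials
        w = lambda x: np.exp(2.0 * (potential.potential(x) - phi0) / s2)
        num, _ = quad(w, x_e, x0, limit=200)
        den, _ = quad(w, x_e, x_c, limit=200)
        return float(num / den)
    raise ValueError(f"unknown method {method!r}")


def transition_rates(
    potential: PotentialSpec, sigma_total: float, fp_method: str = "exact"
):
    """Kramers escape rates (k_C, k_E) per unit t/tau.

    k_C escapes the error attractor (a correcting transition), k_E the
    correct one.  Prefactor sqrt(|phi''(x_att) phi''(x_U)|)/(2 pi), exponent
    -2 (phi(x_U) - phi(x_att)) / sigma^2.
    """
    if sigma_total <= 0:
        raise ValueError("sigma_total must be positive")
    x_e, x_u, x_c = potential.fixed_points(fp_method)
    s2 = sigma_total**2
    curv_u = abs(float(potential.curvature(x_u)))
    phi_u = float(potential.potential(x_u))
    k_c = (
        np.sqrt(abs(float(potential.curvature(x_e))) * curv_u)
        / (2.0 * np.pi)
        * np.exp(-2.0 * (phi_u - float(potential.potential(x_e))) / s2)
    )
    k_e = (
        np.sqrt(abs(float(potential.curvature(x_c))) * curv_u)
        / (2.0 * np.pi)
        * np.exp(-2.0 * (phi_u - float(potential.potential(x_c))) / s2)
    )
    return float(k_c), float(k_e)


def rates_per_second(potential: PotentialSpec, sigma_total: float, tau: float,
                     fp_method: str = "exact"):
    """Escape rates in 1/s for an integrator with time constant ``tau``."""
    k_c, k_e = transition_rates(potential, sigma_total, fp_method)
    return k_c / tau, k_e / tau


def trial_transition_probs(k_c: float, k_e: float, T_over_tau: float):
    """(p_C, p_E, P_inf) for a trial of dimensionless duration T/tau."""
    if T_over_tau < 0:
        raise ValueError("duration must be non-negative")
    k = k_c + k_e
    p_inf = k_c / k if k > 0 else 0.5
    activation = -np.expm1(-k * T_over_tau)
    return float(p_inf * activation), float((1.0 - p_inf) * activation), float(p_inf)


def predict(
    potential: PotentialSpec,
    sigma_total: float,
    T_over_tau: float,
    x0: float = 0.0,
    p0_method: str = "erf",
    fp_method: str = "exact",
) -> KramersPrediction:
    """Full two-state prediction; the two algebraic forms of P must agree."""
    p0 = first_visit_probability(potential, sigma_total, x0, p0_method, fp_method)
    k_c, k_e = transition_rates(potential, sigma_total, fp_method)
    p_c, p_e, p_inf = trial_transition_probs(k_c, k_e, T_over_tau)
    p_chain = p0 * (1.0 - p_e) + (1.0 - p0) * p_c
    decay = np.exp(-(k_c + k_e) * T_over_tau)
    p_relax = p0 * decay + p_inf * (1.0 - decay)
    if abs(p_chain - p_relax) > 1e-12:
        raise AssertionError(
            f"two-state accuracy forms disagree: {p_chain!r} vs {p_relax!r}"
        )
    return KramersPrediction(
        p0=p0,
        k_c=k_c,
        k_e=k_e,
        p_c=p_c,
        p_e=p_e,
        p_inf=p_inf,
        accuracy=p_chain,
        fixed_points=potential.fixed_points(fp_method),
        sigma=sigma_total,
        T_over_tau=T_over_tau,
    )


def accuracy(
    potential: PotentialSpec,
    sigma_total: float,
    T_over_tau: float,
    x0: float = 0.0,
    p0_method: str = "erf",
    fp_method: str = "exact",
) -> float:
    """Trial accuracy P = P0 (1 - p_E) + (1 - P0) p_C."""
    return predict(potential, sigma_total, T_over_tau, x0, p0_method, fp_method).accuracy


def critical_mu(alpha: float) -> float:
    """Tilt above which P(sigma_S) decays monotonically: (alpha/2) sqrt(alpha/2)."""
    return mu_critical(alpha)


def accuracy_local_maximum(
    alpha: float,
    mu: float,
    T_over_tau: float,
    sigma_grid=None,
    refine: bool = True,
    fp_method: str = "exact",
    p0_method: str = "erf",
) -> dict:
    """Locate the interior local maximum of P(sigma) by grid scan.

    P(sigma -> 0) -> 1 for any tilt, so the global maximum always sits at the
    left edge; the bump of interest is a local maximum that follows a local
    minimum as sigma grows (the correcting-transition window).  The scan
    (default 200 log-spaced sigmas in [0.05, 2]) detects that pattern and
    refines the bracket by golden-section search.  ``interior`` reports
    whether such a bump exists on the grid.
    """
    pot = double_well(mu, alpha)
    if sigma_grid is None:
        sigma_grid = np.geomspace(0.05, 2.0, 200)
    sigma_grid = np.asarray(sigma_grid, dtype=float)

    def p_of(s):
        try:
            return accuracy(pot, s, T_over_tau, p0_method=p0_method,
                            fp_method=fp_method)
        except SingleWellError:
            return np.nan

    values = np.array([p_of(s) for s in sigma_grid])
    d = np.sign(np.diff(values))
    # first local minimum, then the first subsequent local maximum
    i_min = None
    i_max = None
    for i in range(1, len(values) - 1):
        if i_min is None and d[i - 1] < 0 <= d[i]:
            i_min = i
        elif i_min is not None and d[i - 1] > 0 >= d[i]:
            i_max = i
            break
    interior = i_max is not None
    if not interior:
        j = int(np.nanargmax(values))
        return {"sigma_max": float(sigma_grid[j]), "p_max": float(values[j]),
                "interior": False, "sigma_min": None,
                "grid_values": values, "grid": sigma_grid}
    s_star, p_star = float(sigma_grid[i_max]), float(values[i_max])
    if refine:
        a, b = sigma_grid[i_max - 1], sigma_grid[i_max + 1]
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        c, e = b - gr * (b - a), a + gr * (b - a)
        for _ in range(60):
            if p_of(c) > p_of(e):
                b = e
            else:
                a = c
            c, e = b - gr * (b - a), a + gr * (b - a)
        s_star = float((a + b) / 2.0)
        p_star = float(p_of(s_star))
    return {"sigma_max": s_star, "p_max": p_star, "interior": True,
            "sigma_min": float(sigma_grid[i_min]),
            "p_min": float(values[i_min]),
            "grid_values": values, "grid": sigma_grid}


def closed_form_sigma_max(alpha: float, T_over_tau: float, z0: float) -> float:
    """Closed-form location of the accuracy maximum, sigma^2 = (alpha^2/2) /
    log(2 T alpha / (pi z0)).

    ``z0`` is an explicit user parameter (it is not fixed by the two-state
    construction here); the numerical locator is the default route.
    """
    arg = 2.0 * T_over_tau * alpha / (np.pi * z0)
    if arg <= 1.0:
        raise ValueError("no interior maximum: log argument must exceed 1")
    return float(np.sqrt(alpha**2 / 2.0 / np.log(arg)))


# ---------------------------------------------------------------------------
# memory-delay switches
# ---------------------------------------------------------------------------

def delay_switch_probability(
    alpha: float, sigma_i: float, tau_s: float, delay_s: float
) -> float:
    """Probability that internal noise flips the stored attractor state
    during an untilted (mu = 0) memory delay.

    Symmetric two-state occupancy: 0.5 * (1 - exp(-2 k_sym * delay/tau)) with
    k_sym the mu = 0 Kramers rate at sigma = sigma_i.
    """
    if sigma_i <= 0:
        return 0.0
    k_sym, _ = transition_rates(double_well(0.0, alpha), sigma_i)
    return float(0.5 * -np.expm1(-2.0 * k_sym * delay_s / tau_s))


def max_internal_noise(
    alpha: float,
    tau_s: float,
    delay_s: float,
    threshold: float = 0.01,
    bracket=(1e-3, 5.0),
) -> float:
    """Largest sigma_I whose delay-switch probability stays at ``threshold``.

    Root-finds delay_switch_probability(sigma_I) = threshold; below the root
    the stored categorical state survives the delay (switch probability under
    threshold), which is the condition for delay-independent accuracy.
    """
    f = lambda s: delay_switch_probability(alpha, s, tau_s, delay_s) - threshold
    lo, hi = bracket
    if f(lo) > 0:
        raise ValueError("threshold already exceeded at the lower bracket")
    if f(hi) < 0:
        # even the strongest amplitude searched cannot switch the state at
        # this barrier/clock (the Kramers prefactor caps the rate): the
        # memory is delay-robust throughout the bracket
        return float(hi)
    return float(brentq(f, lo, hi, xtol=1e-10))
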