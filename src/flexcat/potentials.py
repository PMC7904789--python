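"""Potential landscapes for the one-dimensional decision variable.

The decision variable x(t) diffuses in a scalar potential phi(x).  Three
families cover the models in the package:

* ``linear``:      phi(x) = -mu * x          (drift-diffusion; bounds supplied
                                              separately)
* ``flat``:        phi(x) = 0                (perfect integrator)
* ``double_well``: phi(x) = -mu*x - alpha*x**2 + x**4

For the double well, positive ``mu`` tilts the landscape toward the correct
attractor at positive x; the barrier between the two wells scales with
alpha**2 (height alpha**2/4 at mu = 0).  The two minima exist only for
|mu| < mu_critical(alpha) = (alpha/2)*sqrt(alpha/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("linear", "flat", "double_well")


class SingleWellError(ValueError):
    """Raised when double-well structure is requested but |mu| >= mu_critical."""


def mu_critical(alpha: float) -> float:
    """Tilt above which the double well loses its metastable minimum.

    For |mu| above this value the cubic phi'(x) = 0 has a single real root and
    the landscape is a single tilted well: accuracy decays monotonically with
    the stimulus fluctuations.
    """
    if alpha <= 0:
        raise SingleWellError("no barrier: alpha must be positive")
    return (alpha / 2.0) * np.sqrt(alpha / 2.0)


@dataclass(frozen=True)
class PotentialSpec:
    """A potential family with its drift ``mu`` and barrier parameter ``alpha``.

    ``alpha`` is meaningful only for the ``double_well`` family.
    """

    family: str
    mu: float = 0.0
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown potential family {self.family!r}")
        if self.family == "double_well":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("double_well requires alpha > 0")

    # -- scalar field ------------------------------------------------------
    def potential(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "flat":
            return np.zeros_like(x)
        if self.family == "linear":
            return -self.mu * x
        return -self.mu * x - self.alpha * x**2 + x**4

    def drift(self, x, mu=None):
        """Deterministic force -dphi/dx at ``x``.

        ``mu`` optionally overrides the stored tilt (used when the tilt is a
        per-trial or time-varying stimulus value); it may be an array
        broadcastable against ``x``.
        """
        mu_val = self.mu if mu is None else mu
        x = np.asarray(x, dtype=float)
        if self.family == "flat":
            return np.zeros(np.broadcast_shapes(x.shape, np.shape(mu_val)))
        if self.family == "linear":
            return np.broadcast_arrays(np.asarray(mu_val, dtype=float), x)[0].copy()
        return mu_val + 2.0 * self.alpha * x - 4.0 * x**3

    def internal_force(self, x):
        """Force from the internal dynamics only, excluding the evidence tilt.

        The evidence S(t) enters the integrator directly as drive; the
        potential adds 2 alpha x - 4 x^3 for the double well and nothing for
        the flat/linear families (whose shape is entirely the evidence tilt
        plus, for the bounded models, the bound rule).
        """
        x = np.asarray(x, dtype=float)
        if self.family in ("flat", "linear"):
            return np.zeros_like(x)
        return 2.0 * self.alpha * x - 4.0 * x**3

    def curvature(self, x):
        """phi''(x); enters the Kramers prefactor."""
        x = np.asarray(x, dtype=float)
        if self.family in ("flat", "linear"):
            return np.zeros_like(x)
        return -2.0 * self.alpha + 12.0 * x**2

    # -- fixed points ------------------------------------------------------
    def fixed_points(self, method: str = "exact"):
        """Stationary points (x_error, x_unstable, x_correct) of the double well.

        ``method="exact"`` solves the cubic phi'(x) = 0 numerically and
        requires |mu| < mu_critical(alpha).  ``method="perturbative"`` returns
        the O(mu) expansion x_att = +/- sqrt(alpha/2) + mu/(4 alpha),
        x_unstable = -mu/(2 alpha), which stays defined for any mu (used where
        closed-form accuracies must extrapolate beyond the bifurcation).
        """
        if self.family != "double_well":
            raise SingleWellError("fixed points are defined for the double_well family")
        a, mu = self.alpha, self.mu
        if method == "perturbative":
            s = np.sqrt(a / 2.0)
            return (-s + mu / (4.0 * a), -mu / (2.0 * a), s + mu / (4.0 * a))
        if method != "exact":
            raise ValueError(f"unknown fixed-point method {method!r}")
        if abs(mu) >= mu_critical(a):
            raise SingleWellError(
                f"|mu|={abs(mu):.4g} >= mu_critical={mu_critical(a):.4g}: single well"
            )
        # phi'(x) = -mu - 2 a x + 4 x^3
        roots = np.roots([4.0, 0.0, -2.0 * a, -mu])
        real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
        if real.size != 3:
            raise SingleWellError("cubic has fewer than three real roots")
        return (real[0], real[1], real[2])

    def barrier_heights(self, method: str = "exact"):
        """(phi(x_U)-phi(x_E), phi(x_U)-phi(x_C)): escape barriers seen from
        the error and correct attractors."""
        x_e, x_u, x_c = self.fixed_points(method)
        phi_u = float(self.potential(x_u))
        return (phi_u - float(self.potential(x_e)), phi_u - float(self.potential(x_c)))


def double_well(mu: float = 0.0, alpha: float = 1.0) -> PotentialSpec:
    return PotentialSpec("double_well", mu=mu, alpha=alpha)


def linear(mu: float = 0.0) -> PotentialSpec:
    return PotentialSpec("linear", mu=mu)


def flat() -> PotentialSpec:
    return PotentialSpec("flat")
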