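# Methods

This note documents the models implemented in `flexcat`, the assumptions
behind them, the numerical choices that matter, and what the synthetic-data
generators do and do not emulate.

## The decision-variable diffusion

All one-dimensional models describe a decision variable x(t) that integrates
momentary evidence S(t) under internal noise:

    tau dx/dt = S(t) - dphi_int/dx + sigma_I xi_I(t),
    S(t) = mu + sigma_S xi_S(t)

where `phi_int` is the internal part of a scalar potential.  Four model
variants differ only in the potential/bound structure:

| model | potential          | bounds      | characteristic kernel |
|-------|--------------------|-------------|-----------------------|
| PI    | flat               | none        | flat (uniform weighting) |
| DDMA  | linear (tilt = S)  | absorbing B | primacy (decaying)    |
| DDMR  | linear (tilt = S)  | reflecting B| recency (rising)      |
| DWM   | -mu x - a x^2 + x^4| none        | primacy -> flexible -> recency |

For the double well (DWM), the two minima are the decision attractors, the
barrier between them scales as alpha^2/4, and the tilt mu biases the correct
side.  Two minima exist only for |mu| < mu_C = (alpha/2) sqrt(alpha/2).

**Integration scheme.**  Euler-Maruyama with dt = tau/40 (tau = 200 ms
default, so dt = 5 ms):

    x(t+dt) = x(t) + (dt/tau) (S + 2 alpha x - 4 x^3)
              + sqrt(dt/tau) sigma_I xi_I

Frame-based stimuli are held piecewise-constant within a frame.  Two
couplings cover every generator:

* *noise-coupled* ensembles (Gaussian frames, exactly-zero-integral frames)
  contribute their per-trial mean as drift and their zero-mean residual once
  per frame with the sqrt(frame/tau) noise scaling, so the integrated
  stimulus variance matches the equivalent white-noise process regardless of
  dt.  When the frame grid equals the integration step this reduces exactly
  to the update above.
* *drift-coupled* ensembles (brightness differences, injected currents) act
  as the momentary tilt S(t) directly and carry their fluctuations in the
  frame values; the engine then adds no separate stimulus noise.

The choice is the sign of x at stimulus offset; an exact tie is broken by a
seeded fair coin.  For the double well the engine also records the first
attractor basin entered and every subsequent switch with a full-hysteresis
detector: a trial "enters" an attractor when x crosses the attractor
position (root of phi'), and a switch requires reaching the *opposite*
attractor position.  This suppresses chatter near the barrier top and
matches the two-state abstraction used by the theory.  Halving dt changes
cell accuracies by less than two binomial standard errors (tested).

The bound magnitude for DDMA/DDMR defaults to B = 1 in evidence units; only
the ratio of the noise amplitudes to B matters, so B is configurable rather
than meaningful.

## Psychophysical kernels

The kernel PK(t) is the rank-based AUROC (Mann-Whitney) between the
per-time-bin stimulus fluctuations of rightward- versus leftward-choice
trials, after removing each trial's generative mean so the two groups are
not separated trivially by net evidence.  For sub-frame stimuli the
fluctuations are binned at tau/10 = 20 ms by default (a signal-to-noise
choice; configurable).

Two summaries condense a kernel:

* **normalized area** - trapezoidal integral of PK - 0.5 divided by the same
  integral for an ideal observer (perfect integrator, sigma_I = 0) on the
  same stimulus ensemble.  1 means fluctuations are integrated as well as
  possible, 0 not at all.
* **normalized slope** - the kernel is scaled to unit area, then fit with
  beta_0 + k beta_1 t where k = 1/(2 var(t)) (population variance of the bin
  centers).  A kernel concentrated entirely at the end maps to +1, at the
  start to -1.  Kernels whose early part dips below 0.5 can nominally
  overshoot the interval; the slope is clipped back to [-1, 1].  The
  area normalization divides by the kernel area and is therefore
  ill-conditioned when that area is near zero (network kernels at moderate
  fluctuation levels); cross-condition orderings in that regime use the
  plain least-squares slope of PK(t) instead (`pk_raw_slope`).

Bootstrap bands resample trials jointly (stimulus and choice together),
1000 repetitions by default, reporting the per-bin standard deviation.

## Kramers two-state theory for the double well

When the barrier is large relative to the noise intensity (the diffusion
constant is sigma^2/2 with sigma^2 = sigma_I^2 + sigma_S^2), the double-well
dynamics reduce to a two-state Markov chain:

* **First visit.**  P0 = splitting probability of reaching the correct
  attractor before the error one from x0, with density exp(2 phi/sigma^2).
  The default closed form completes the square of the quadratic part of the
  potential and neglects the quartic term near the barrier top, giving a
  ratio of error functions; `method="quadrature"` integrates the exact
  expression.  The erf form is accurate to <0.01 for sigma <~ 0.3 at
  alpha ~ 1 but acquires a visible bias at larger noise, so the tests that
  compare theory against simulation at Monte-Carlo precision use the
  quadrature mode.
* **Rates.**  Kramers escape rates with curvature prefactor
  sqrt(|phi''(x_att) phi''(x_U)|)/(2 pi) and exponent
  -2 (phi(x_U) - phi(x_att))/sigma^2, per unit dimensionless time t/tau
  (divide by tau for 1/s).  Their ratio at small tilt is
  exp(4 mu sqrt(alpha/2)/sigma^2): correcting transitions are exponentially
  favored, which is the mechanism behind every non-monotonicity in the
  package.
* **Fixed points.**  The exact stationary points are the roots of the cubic
  phi'(x) = 0.  The O(mu) expansion is x_att = +/- sqrt(alpha/2) +
  mu/(4 alpha) and x_U = -mu/(2 alpha); note the unstable point moves as
  -mu/(2 alpha) (linearizing -mu - 2 alpha x = 0), not -mu/(4 alpha).
* **Trial probabilities and accuracy.**  p_C = P_inf (1 - e^{-kT}),
  p_E = (1 - P_inf)(1 - e^{-kT}) with k = k_C + k_E and P_inf = k_C/k; the
  accuracy P = P0 (1 - p_E) + (1 - P0) p_C is algebraically identical to the
  relaxation form P0 e^{-kT} + P_inf (1 - e^{-kT}), and the implementation
  evaluates both and asserts agreement to 1e-12.

**Validity.**  The rate formula is asymptotic in barrier/noise.  Measured
equilibrium switch rates agree with the formula to ~1% at barrier =
2.8 sigma^2 and ~15% at barrier = 2.3 sigma^2; outside barrier >= 2 sigma^2
the formula overestimates rates badly and the package makes no quantitative
claims there.  The interior maximum of P(sigma_S) exists for 0 < mu < mu_C
and long trials and is located by a grid scan with golden-section
refinement; a closed-form location involving an undetermined constant z0 is
available behind a flag with z0 as an explicit user parameter.

**Memory delays.**  With mu = 0 and only internal noise, the stored state
flips with probability 0.5 (1 - exp(-2 k_sym delay/tau)).  Root-finding the
sigma_I at which this reaches 1% over the longest (1.08 s) delay of the
two-pulse task at the fitted parameters (alpha = 0.70, tau = 3.3 s) gives
sigma_I^max = 0.32; when even the strongest amplitude in the search bracket
cannot reach the threshold (tiny barrier or very slow clock - the prefactor
caps the rate), the bracket top is returned.

## Double-pass consistency

Consistency is the probability that two presentations of the identical
stimulus realization, under independent internal noise, yield the same
choice.  Only exactly-zero-integral stimuli are used (each row z-scored to
mean 0, sd sigma_S), so consistency cannot rise trivially through trials
with large net evidence.  Per stimulus the estimator is the fraction of
concordant unordered pass pairs, (n_R(n_R-1) + n_L(n_L-1))/(n(n-1)) - the
unbiased U-statistic for p^2 + (1-p)^2 at any pass count.  The default is
20 passes per stimulus (the generative process is under our control; more
passes sharpen the per-stimulus estimate); a strict 2-pass mode reproduces
the experimental protocol.

The companion diagnostic runs identical stimuli with and without internal
noise and reports the difference in per-trial switch probability; the
consistency dip coincides with the peak of this difference - the regime
where transitions need internal and stimulus noise to cooperate.

## Two-pulse working-memory analysis

Condition accuracies chain the two-state theory through 120 ms pulses with
drift mu = k coh and are delay-independent by construction; the delay
compatibility is bounded separately through sigma_I^max.  Because the
maximum-likelihood coherence scaling puts k * 25.6 and k * 51.2 beyond the
double-well bifurcation, the closed forms use the O(mu) perturbative fixed
points throughout, which remain defined for every tilt and extrapolate
monotonically.

The fit maximizes the binomial log-likelihood
sum_i [N_C,i log P_i + N_E,i log(1 - P_i)] over (k, alpha, sigma, tau) with
Nelder-Mead from Latin-hypercube restarts plus simplex polishing.  (A
within-package flag also evaluates the linear form sum N_C P + N_E (1-P);
it is not a likelihood - its optimum saturates at P in {0, 1} - and exists
for comparison only.)

**Interval estimation.**  The likelihood surface is a soft ridge: the
pooled accuracies constrain (k, alpha, sigma) only through the first-visit
geometry, and tau enters only through within-pulse transition probabilities
of order 10^-2.  Finite-difference Hessian (Wald) intervals at the MLE
extrapolate a quadratic along this ridge and badly under-cover (the
log-likelihood 10 units of tau away from the MLE can be less than one unit
worse).  The reported `ci95` are therefore profile likelihood-ratio
intervals - endpoints where the profiled negative log-likelihood rises by
chi2_{0.95,1}/2 - located by geometric bracketing and secant refinement with
warm-started inner optimizations.  The Wald intervals are retained in
`meta["ci95_wald"]`.  Parameter-recovery tests check that the truth falls
inside the reported intervals and that interval coverage over replicated
synthetic tables is at least nominal-ish (>= 90%).

**Perfect-integrator comparison.**  The delay curves compare the double
well against a perfect integrator with mu_PI = 0.44 k coh whose accumulated
evidence is Gaussian: mean (mu_1 + mu_2) T_p / tau, variance
(2 T_p sigma^2 + T_delay sigma_I^2)/tau - total noise diffuses during the
pulses, internal noise alone during the delay.  This bookkeeping is the
package's construction; its role is the qualitative contrast (diffusive
memory decays with delay for any nonzero sigma_I, categorical memory does
not until delay switches activate).

**Units.**  tau is in seconds; the fitted value 3.3 is interpreted as
seconds because the Kramers rates divided by that tau reproduce the
sub-percent delay-switch regime over the task's 1.08 s delay that the
delay-flat accuracies require.

**PRI.**  The primacy-recency index is (b2 - b1)/(b1 + b2) from a logistic
regression of correctness on the two pulse coherences (separation triggers
an L2-regularized refit).  At the reported parameters the closed-form chain
gives a strongly negative (primacy) model PRI: with tau = 3.3 s a 120 ms
pulse activates transitions with probability ~10^-2, so the second pulse
moves accuracy far less than the first pulse's splitting probability.  The
package asserts the definition's limits and the decrease of PRI with
barrier height, not a particular sign at the fitted point.

## Spiking network (reduced scale)

Two populations of excitatory current-based LIF neurons (selective for the
two choices) compete through one untuned inhibitory population.  Sparse
random connectivity (p = 0.1); exponential synapses with a 0.5 ms delay; a
2 ms refractory period; external Poisson drive through instantaneous
synapses; stimulus = two Ornstein-Uhlenbeck currents (20 ms correlation
time, exact AR(1) updates) with means I0 (1 +/- mu) and sd sigma_S injected
into the excitatory populations.  Voltages are in mV with currents folded
through the leak conductance, so "pA" scales map to mV equivalents.

The default sizes (200+200 excitatory, 100 inhibitory) are a five-fold
reduction of the 1000+1000/500 architecture, with recurrent weights scaled
by the inverse factor to preserve mean recurrent drive (`full_scale`
restores the large network).  The synaptic weights, external rates and I0
are package-tuned - no published values exist for this reduced variant - by
the documented procedure: (a) without stimulus the symmetric low-rate state
is stable for seconds; (b) with the stimulus baseline I0 the network
reliably develops winner-take-all (one population at ~30 Hz, the other
silent); (c) a transient kick decides the winner and the attractor persists
>= 1 s (the `check_attractor_persistence` self-check, which raises a
configuration error with a tuning hint when it fails).

By default the external Poisson input enters in its diffusion limit (per
step: mean + Gaussian of matched variance); `external_mode="poisson"` draws
exact Poisson counts (~2x slower, statistically indistinguishable at the
default 3900 Hz x 0.1 ms).  Euler step 0.1 ms.  The choice is the
population with more spikes over the last 100 ms; count ties break by a
seeded coin, and a fully silent readout window flags the trial undecided
(excluded from accuracy with its count reported).  Kernels are computed by
reverse-correlating the choice against the injected current difference
binned at 100 ms.  Every trial redraws connectivity, initial conditions,
external input and stimulus from separate named streams.

Only orderings are asserted at this scale (accuracy non-monotonicity in
sigma_S at long durations; kernel slope increasing with sigma_S and with
duration), not absolute values.  Network kernels are compared on the
least-squares PK slope against *fractional* trial time: the per-second
slope scales like 1/T for a fixed kernel shape, and the unit-area
normalization is unstable when the kernel area is near zero.

Two reduced-scale limitations are worth stating plainly.  First, the
accuracy *recovery* at strong fluctuations (the correcting-transition
window) does not reliably materialize at this scale: accuracy declines
from the weak-fluctuation level into a dip and then plateaus near chance,
with run-to-run differences at a few hundred trials per condition as large
as any residual recovery; accuracy can even dip slightly below chance at
intermediate fluctuation strengths, which the correcting-transition
mechanism cannot produce and which points to a small-network dynamical
artifact (the delayed inhibition can flip an early winner).  The decline
into the dip is robust; the recovery is asserted only as an ordering and
may fail at this scale.  Second, at fluctuation levels strong enough to
drive transitions, *short* (1 s) trials produce recency-leaning kernels
rather than the primacy seen at larger scale: the winner-take-all
resolution occupies a large fraction of a short trial at this size, so the
choice is dominated by the state formed late in the trial.  The duration
ordering of the kernel slope is therefore evaluated in the weak-fluctuation
regime, where it reflects the intended mechanism (longer trials leave less
of the stimulus after the categorization locks in).

## n-choice rate network

Standard coupled rate equations for n in {3, 4} excitatory populations and
one inhibitory population with transfer phi(x) = 0 / x^2 / 2 sqrt(x - 3/4)
(continuous and increasing), s = 0.694, c = g = sqrt(5), tau = 20 ms,
tau_I = 10 ms, I = 2.25, Delta I = 0.03 s, inhibitory noise 0.  Euler step
0.1 ms; trial duration defaults to 2 s (not fixed by anything else; a
documented choice); accuracy is the fraction of trials in which the
up-weighted population has the highest rate at the end; rate ties break by
a seeded coin.

## Synthetic stimulus generators

The generators define the study conditions; their defaults are fixed once:

* Gaussian frames: i.i.d. Normal(mu, sigma_S^2) per frame on the
  integration grid.
* Zero-integral frames: rows z-scored exactly (mean 0, sd sigma_S to
  machine precision); the constraint makes each trial a bridge-like
  fluctuation with no net evidence.
* Brightness discs: 100 ms frames, five equal segments, an evidence pulse
  in 80% of trials (congruent or incongruent with equal probability, random
  segment) exactly compensated across the remaining segments, which makes
  segment deviations anticorrelated.  The luminance-to-evidence scaling of
  the original display is not available, so the generative defaults
  (mean gap 0.2, frame sd 0.4, pulse 0.4) are structural choices placing
  the driven double-well observer (alpha = 0.8, sigma_I = 0.3, tau =
  200 ms) at intermediate accuracy inside the duration-crossover regime.
  The emulation is structural, not calibrated to luminance units.
* Two-pulse design: 6 single-pulse coherences and the 9 ordered coherence
  pairs from {3.2, 6.4, 12.8}% crossed with delays {0, 120, 360, 1080} ms,
  always congruent.
* OU currents: exact conditional-Gaussian updates, stationary
  initialization.

What the generators do *not* emulate: sensory transduction nonlinearities,
lapses, sequential dependencies, subject heterogeneity, or the actual
visual stimuli (only evidence traces).  Tests passing on these ensembles
show that the analysis chain recovers the dynamics it assumes; they do not
certify behavior on real psychophysical data, which can violate those
assumptions.

## Reproducibility and problem sizes

Every source of randomness draws from a named, counter-based stream
(stimulus, internal, connectivity, init, external, bootstrap, fit) derived
from one master seed, so regenerating stimuli never perturbs internal-noise
draws.  Identical seeds give bit-identical stimuli and byte-identical
pipeline tables.

Default experiment sizes in the test suite and pipelines are desk-scale
choices that keep each analysis comfortably resolvable: 3000-10000 trials
per psychometric cell, 6000 trials per kernel, 400 stimuli x 20 passes per
consistency point, 200 trials per spiking cell at the reduced network
scale, 100 replicate tables for interval coverage.  The same code runs at
larger sizes unchanged.
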