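# flexcat

Attractor dynamics of perceptual evidence integration: simulation and
analysis tools for the question *when during a stimulus does the evidence
drive the choice, and can stimulus fluctuations help rather than hurt?*

Canonical bounded-integration models make fixed predictions: a perfect
integrator (PI) weights evidence uniformly, a drift-diffusion model with
absorbing bounds (DDMA) over-weights early evidence (primacy), one with
reflecting bounds (DDMR) over-weights late evidence (recency).  A
winner-take-all attractor — diffusion of a decision variable x in the
double-well potential

    phi(x) = -mu x - alpha x^2 + x^4,     tau dx/dt = -phi'(x) + sigma_S xi_S + sigma_I xi_I

moves *between* these regimes as the stimulus fluctuation magnitude
sigma_S or the duration T varies, because fluctuations can drive
transitions between the two decision attractors, and the transitions that
correct an initial error are exponentially more likely than those that
produce one (Kramers rate asymmetry).  The measurable signatures: a
psychophysical-kernel slope sweeping from primacy to recency, a
*non-monotonic* psychometric curve P(sigma_S), a dip in double-pass choice
consistency, and delay-independent accuracy when the attractor stores the
decision across a working-memory gap.

The package is aimed at computational and psychophysical researchers who
want to simulate these models, analyze synthetic (or their own) trial data
with reverse correlation, and fit the attractor model's closed-form
accuracy theory.

## What is inside

| module | contents |
|--------|----------|
| `flexcat.stimuli` | seeded generators: Gaussian frame streams, exactly-zero-integral stimuli, two-disc brightness traces with compensated evidence pulses, the two-pulse condition design, Ornstein-Uhlenbeck stimulus currents |
| `flexcat.models` | one Euler-Maruyama engine for PI / DDMA / DDMR / double-well, with choice, first-visited-attractor and transition bookkeeping; psychometric sweeps |
| `flexcat.kernels` | psychophysical kernels (rank-based AUROC per time bin), normalized area and slope, bootstrap bands |
| `flexcat.theory` | Kramers two-state accuracy theory: splitting probability, escape rates, per-trial transition probabilities, the critical tilt, memory-delay switch probabilities and the internal-noise bound |
| `flexcat.consistency` | double-pass consistency with an unbiased pair estimator, plus the internal-noise transition diagnostic |
| `flexcat.pulsefit` | two-pulse working-memory analysis: closed-form condition accuracies, maximum-likelihood fitting with profile-likelihood CIs, primacy-recency index, delay-robustness bound and the perfect-integrator comparison |
| `flexcat.spiking` | reduced-scale winner-take-all network of current-based LIF neurons (numba) |
| `flexcat.ratenet` | n-choice (3 or 4) winner-take-all rate network |
| `flexcat.pipelines`, `flexcat.cli` | YAML-configured pipelines, `flexcat` console script, desk-scale `reproduce` bundles |

## Worked example

Predict the accuracy of the double-well model near its
flexible-categorization point and check it against simulation:

```python
import numpy as np
from flexcat import theory, stimuli, kernels
from flexcat.models import IntegratorConfig, simulate
from flexcat.potentials import double_well

# tilt mu=0.15, barrier parameter alpha=1, noise sigma_S=0.44, T = 10 tau
pred = theory.predict(double_well(0.15, 1.0), 0.44, 10.0, p0_method="quadrature")
print("P0  =", round(pred.p0, 3))        # P0  = 0.648
print("p_C =", round(pred.p_c, 3),       # p_C = 0.54  p_E = 0.071
      " p_E =", round(pred.p_e, 3))
print("P   =", round(pred.accuracy, 3))  # P   = 0.792

st  = stimuli.gaussian_frames(4000, 400, mu=0.15, sigma_s=0.44, seed=1)
ens = simulate(st, double_well(0.15, 1.0), None, IntegratorConfig(seed=1))
print(round(ens.accuracy(), 3))                      # 0.775
print(round(float(np.mean(ens.n_transitions > 0)), 3))  # 0.186
kr = kernels.compute_pk(st, ens.choices)
print(round(kr.slope, 3))                            # -0.129
```

Reading: only 65% of trials fall into the correct attractor first
(`P0 = 0.648`), but correcting transitions (`p_C = 0.54`) vastly outnumber
error-generating ones (`p_E = 0.071`), lifting the accuracy to 0.79 —
*above* what less-fluctuating stimuli at sigma_S ≈ 0.28 achieve (≈ 0.73).
The simulation (4000 trials) agrees within sampling error, 19% of trials
show at least one attractor switch, and the kernel slope sits near zero:
the flexible-categorization regime.

The internal-noise ceiling compatible with delay-independent accuracy in
the two-pulse task, at the fitted parameters (alpha = 0.70, tau = 3.3 s,
total sigma = 0.52):

```python
theory.max_internal_noise(alpha=0.70, tau_s=3.3, delay_s=1.08)  # 0.3247...
```

From the shell, the same machinery:

```bash
flexcat theory --alpha 1.0 --mu 0.15 --sigma 0.44 --T 2.0 --out out/theory
flexcat pk --model dwm --sigma-s 0.1,0.3,0.58,1.0 --trials 2000 --out out/pk
flexcat reproduce fig3   # accuracy-vs-sigma_S table with theory overlay
```

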