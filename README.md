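# transdermal

Tools for **transdermal alcohol biosensing**: estimating breath alcohol
concentration (BrAC) from the transdermal alcohol concentration (TAC) signal
measured by a wearable skin sensor, with principled uncertainty.

Wearable sensors such as the SCRAM bracelet measure ethanol in perspiration
vapor at the skin surface rather than in breath or blood. The map from BrAC to
TAC is a smoothed, delayed, subject- and device-dependent filtering of the
drinking episode, so researchers in alcohol epidemiology and clinical studies
who want BrAC — the quantity with established interpretation — must invert
that map. This package implements the full pipeline:

1. a physics-based **forward model** of ethanol transport through the
   epidermis into the sensor's collection chamber,
2. **Bayesian estimation** of the model's physiological parameters from
   paired BrAC/TAC training episodes, and
3. regularized, nonnegativity-constrained **deconvolution** of BrAC from a
   TAC record, weighted by the parameter posterior, with conservative
   credible bands.

## Model

Ethanol concentration `x(t, η)` in the (nondimensionalized) epidermal layer
`η ∈ [0, 1]` obeys a diffusion equation coupled to a well-stirred collection
chamber `w(t)`:

    ∂x/∂t = q1 ∂²x/∂η²,
    dw/dt = q3 ∂x/∂η(t, 0) − q4 w(t),        x(t, 0) = w(t),
    q1 ∂x/∂η(t, 1) = q2 u(t),                y(t) = w(t),

with BrAC `u` entering as a flux at the dermal boundary and TAC `y` read from
the chamber. `q1` (effective diffusivity over squared skin thickness, 1/hr)
and `q2` (input gain, 1/hr) are subject-dependent unknowns; `q3`, `q4`
(chamber inflow/outflow, 1/hr) are device constants, fixed to 1 by default.

A Galerkin projection onto `n + 1` linear B-splines and zero-order-hold
sampling at interval `τ` (default 5 min) turn this into an exact discrete
convolution `y_k = Σ_j h_{k−j−1}(q) u_j` with filter
`h_i = Ĉ Â(q)^i B̂(q)`, `Â = exp(A τ)`. Measured TAC is `V_j = y_j + ε_j`
with i.i.d. Gaussian noise; a truncated bivariate normal prior on
`q = (q1, q2)` over a rectangle `Q` yields a posterior that is sampled by
random-walk Metropolis–Hastings and summarized by its mean and the smallest
ball around it containing 90% of the draws (the *credible circle*).

Deconvolution estimates `u(t; q)` jointly over time (linear splines) and a
cell partition of `Q` (posterior histogram weights) by solving

    min_{U ≥ 0} ‖[H ; (r1 Q1 + r2 Q2)^{1/2}] U − [ŷ ; 0]‖²,

where `H` stacks the per-cell convolutions weighted by posterior mass and
`Q1`, `Q2` penalize the squared value and derivative norms. The population
BrAC estimate is the posterior-weighted mean curve; evaluating the per-cell
curves at posterior draws gives a pointwise quantile band.

Since real paired BrAC/TAC sessions are not publicly distributable, a
synthetic-data module generates drinking episodes (single / dual / steady
drinking patterns, calibrated peak-TAC-to-noise ratios) so that every stage is
testable end to end.

## Worked example

```python
import numpy as np
from transdermal import (
    ModelParameters, NoiseModel, RegularizationWeights, default_prior,
    generate_cohort, idealized_designs, fit_posterior, credible_circle,
    generate_episode, build_population_measure, build_population_system,
    deconvolve, credible_band,
)

q0 = ModelParameters(q1=1.0, q2=1.0)          # true physiological parameters
noise = NoiseModel(sigma=0.025)               # TAC measurement noise (SNR ~ 8)
prior = default_prior()

episodes = generate_cohort(10, q0, idealized_designs(noise.sigma), noise, n=8, seed=1)
chain = fit_posterior(prior, episodes, noise, n=8, n_draws=1500, burn_in=100, seed=2)
circle = credible_circle(chain, level=0.90)
print(f"posterior mean  = ({circle.center[0]:.3f}, {circle.center[1]:.3f})")
print(f"90% credible radius = {circle.radius:.3f}")

test = generate_episode(idealized_designs(noise.sigma)[2], q0, noise, n=8, seed=99)
measure = build_population_measure(chain, 20, 20, prior.domain)
system = build_population_system(measure, n=8, m=96, tau=test.tau, K_steps=len(test) - 1)
result = credible_band(deconvolve(test.tac, system, RegularizationWeights(1e-3, 1e-2)), chain)
k = int(np.argmax(result.mean_curve))
print(f"estimated BrAC peak = {result.mean_curve[k]:.3f} at t = {result.times[k]:.2f} hr")
```

prints

```
posterior mean  = (1.067, 1.052)
90% credible radius = 0.051
estimated BrAC peak = 0.429 at t = 1.00 hr
```

Ten noisy training episodes generated at `q0 = (1, 1)` recover the true
parameters to within ~0.08 with a tight 90% credible circle, and the
deconvolution of a held-out noisy TAC record locates the BrAC peak at the
correct time (the true peak was 0.571 at t = 1.00 hr; amplitude is somewhat
attenuated by regularization and measurement noise).

The same pipeline is available from the shell:

```
transdermal simulate --seed 1 --out cohort -R 10
transdermal fit-posterior --seed 2 --out fit cohort/episode_*.csv
transdermal deconvolve --chain fit/chain.csv --tac cohort/episode_000.csv --out brac.csv
transdermal consistency-exp --seed 1 --out report.csv --cohorts 1,10,50 --seeds 10
```

## Layout

- `src/transdermal/forward.py` — Galerkin assembly, impulse filter, convolution
- `src/transdermal/bayes.py` — likelihood, truncated-normal prior, MH sampler,
  credible circles, posterior surfaces
- `src/transdermal/deconv.py` — population measure, block system, NNLS
  deconvolution, credible bands, regularization tuning
- `src/transdermal/synthetic.py` — episode designs, cohort generation,
  grid resampling
- `src/transdermal/config.py`, `cli.py` — YAML config validation, episode file
  I/O, command-line drivers
- `docs/methods.md` — modeling and numerical choices in detail
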