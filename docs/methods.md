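# Methods

This note records the model, the numerical choices, and the reasoning behind
the defaults, in the order the pipeline runs.

## Forward model

The skin/sensor system is a hybrid PDE/ODE: one-dimensional diffusion of
ethanol through the epidermal layer (nondimensionalized depth `η ∈ [0, 1]`)
coupled to a first-order inflow/outflow compartment for the sensor's vapor
collection chamber. After the change of variables that absorbs the skin
thickness and physical rate constants, four positive parameters remain:

| parameter | meaning | units | default |
|---|---|---|---|
| `q1` | effective diffusivity / thickness² | 1/hr | estimated |
| `q2` | BrAC input gain | 1/hr | estimated |
| `q3` | chamber inflow gain | 1/hr | 1 (device constant) |
| `q4` | chamber outflow rate | 1/hr | 1 (device constant) |

`q3` and `q4` are hardware properties, treated as bench-measurable and fixed;
only `(q1, q2)` are inferred. The constant-input steady state gives the exact
identity `gain = q2·q3/(q1·q4)`, used throughout the tests as a closed-form
oracle.

**Discretization.** The weak form is projected onto the span of `n + 1`
linear B-splines (hat functions) on a uniform mesh. The state inner product
carries a `q1/q3` point mass at the skin surface, so the mass matrix is the
exact hat-function Gram matrix with `q1/q3` added at entry (0, 0); the
stiffness matrix is `q1` times the derivative Gram plus `q1·q4/q3` at (0, 0).
Gram integrals of piecewise-linear products are evaluated in closed form — no
quadrature error. The one-step transition matrix is the dense matrix
exponential `Â = exp(−M⁻¹K·τ)` (scaling-and-squaring Padé); with `n ≤ 64`
this is cheap and introduces no time-stepping error. The zero-order-hold
input vector is assembled as `B̂ = (I − Â)(Ξ + K⁻¹ e₀ q2)` with
`Ξ = (q2/q1)·(0, 1/n, …, 1)ᵀ`; the simplification of the load term to
`K⁻¹ e₀ q2` holds because only the first basis function is nonzero at the
surface. Both forms of `B̂` circulating in the literature (via `−A⁻¹M⁻¹` or
`+K⁻¹`) are algebraically identical since `A = −M⁻¹K`; the implementation is
validated against the steady-state gain and impulse-response positivity
rather than either printed form.

**Filter and convolution.** TAC is the discrete convolution of BrAC with
`h_i = Ĉ Â^i B̂`, computed by iterated matrix–vector products (never by
forming `Â^i`). FEM sign noise can make individual coefficients negative at
the `1e−10` level; these are clamped to zero since the physical impulse
response is nonnegative. The filter horizon defaults to the episode length —
the convolution is finite, so no tail is needed. Time index `k` means
`t = k·τ`; `y₀ = 0` always (zero initial conditions). The default sampling
interval is `τ = 1/12 hr` (5 min), the rate to which sensor records are
conventionally resampled. BrAC and TAC are carried as dimensionless
concentration fractions; no unit conversion is performed.

## Likelihood, prior, posterior

Measured TAC is the model output plus i.i.d. `N(0, σ²)` noise, independent
across episodes and time points. The time-`0` samples are identically zero on
both sides (episodes begin sober) and are excluded from the likelihood
product. `σ` is treated as known and set per experiment (no hyperprior):
`σ = 0.005` in the low-noise regime and `σ = 0.025` in the noisy regime.
Episodes are treated as independent even when they come from the same subject
or from two devices worn simultaneously — a deliberate simplification.

The prior on `(q1, q2)` is a bivariate normal truncated to the rectangle
`Q = [0.01, 2.2877] × [0.01, 2.1410]`, with mean `(0.6318, 1.0295)` and
covariance `[[0.0259, 0.0077], [0.0077, 0.1232]]` — an informative prior
representing accumulated population knowledge. Its normalization over `Q` is
computed once from the bivariate normal CDF; prior draws for oracle checks
use rejection sampling.

**Sampler.** Random-walk Metropolis–Hastings with isotropic Gaussian
proposals, initialized at the prior mean. The proposal scale is adapted
toward 20–40% acceptance during burn-in only (multiplied/divided by 1.5 every
25 proposals) and frozen afterwards, so the retained draws are a valid MH
chain. Proposals outside `Q` get `−∞` log posterior and are rejected, which
is exactly the truncation. Default run length 1500 draws with 100 burn-in.
Chains are bit-reproducible under a fixed seed.

**Summaries.** The *credible circle* is the smallest Euclidean ball about the
posterior mean containing the stated fraction (default 90%) of retained
draws: center = sample mean, radius = the level-quantile of distances to the
center. (Distance metric and center are a convention choice; mean + Euclidean
quantile is used and documented rather than inferred.) Posterior *surfaces*
evaluate the unnormalized posterior on a uniform lattice over `Q` and
normalize by trapezoidal quadrature — an MCMC-free route to the same
distribution that doubles as the evidence estimate.

## Deconvolution

The estimated input `u(t; q)` is a function of time *and* the uncertain
parameters, expanded in a tensor-product basis: linear splines on `[0, T]`
(`m` intervals) crossed with the indicators of an `m1 × m2` cell partition of
`Q`. The parameter measure is piecewise constant on the cells — by default
the histogram of posterior draws; alternatively cell quadrature of a
normalized surface (integrated on an 8×8 subgrid per cell, since cell-center
sampling misplaces mass when the posterior is sharply peaked). The parameter
grid is ascending, `a_i + (b_i − a_i)j/m_i`. Only positive-mass cells enter
the solve; zero-mass cells contribute nothing to predictions, the norm, or
the band.

The objective stacks the measure-weighted per-cell convolution blocks over
the Cholesky factor of `r1·Q1 + r2·Q2` (with `1e−12` diagonal jitter for PSD
safety), so a single nonnegative least-squares solve minimizes data misfit
plus the squared regularization norm. The solver is scipy's active-set NNLS
up to 1200 unknowns, switching to the bound-constrained trust-region solver
(`lsq_linear`) beyond that. Solutions are verified against the KKT conditions
in the tests.

Because every episode begins at zero concentration, the first time-basis
function is dropped by default (`zero_start=True`), pinning `u(0) = 0`;
without this the weakly-determined initial coefficient absorbs spurious mass.

**Bands.** Each retained posterior draw is mapped to its cell's curve
(nearest positive-mass cell if its own is empty — the estimate is piecewise
constant in `q` by construction), and the band is the pointwise
`(1 ± level)/2` quantile envelope, clipped to contain the mean curve. A
point-mass posterior collapses the band onto the single curve.

**Regularization weights.** `(r1, r2)` can be tuned on training episodes by
minimizing summed squared BrAC reconstruction error plus TAC re-simulation
error over a log-spaced candidate grid (ties toward the smoother solution).
Re-simulation feeds the per-cell deconvolved input back through the per-cell
convolution and then takes the measure expectation; taking the expectation
after re-simulation is a documented choice, not asserted as the only reading.
The package defaults `r1 = 1e−3, r2 = 1e−2` are the values this tuner selects
on representative synthetic training episodes in the noisy regime.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
episodes start and end at zero, BrAC rises linearly during one of three
drinking patterns (single: 15 min; dual: two 15-min windows 30 min apart;
steady: 60 min) and decays exponentially (default time constant 0.75 hr,
clamped to zero below `1e−4` of peak), TAC is the forward-model output plus
i.i.d. Gaussian noise with the first sample forced to zero. Episode seeds are
derived deterministically from a master seed; optional jitter perturbs peak
(±10%) and onset timing.

Two preset regimes calibrate the peak-TAC-to-noise ratio: ~20 at `σ = 0.005`
and ~8 at `σ = 0.025`. The skin/chamber dynamics attenuate a multi-hour
episode's peak by a factor ≈ 0.36 at `q = (1, 1, 1, 1)`, so the preset peak
BrAC values (≈ 0.55 in the noisy regime) sit above the typical human breath
range (0.02–0.12); `realistic_designs()` provides human-range peaks when SNR
calibration is not needed. TAC generated for the likelihood is *not* clamped
at zero — the Gaussian noise model admits negative values; clamping would
bias inference.

What the generator does **not** emulate: ingestion/absorption pharmaco-
kinetics, model misspecification (the TAC truly is the forward model plus
white noise), within-subject correlation between episodes or between two
devices on the same person, sensor drift, and temperature/humidity effects.
Passing tests therefore demonstrate correctness of the algorithms under the
model's own assumptions, not field accuracy on real sensors.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` use: Galerkin dimension `n = 8`
for inference (reference `n = 64` for convergence checks, `n = 24` for data
generation in the surface study), episodes of 8 h at `τ = 1/12 hr` (97
samples), MH chains of 1500 draws / 100 burn-in, cohorts of R = 1, 10, 50
episodes with 10 replicate seeds, deconvolution at `m = 96` time intervals on
a 20 × 20 parameter grid, and 150 × 150 lattices for posterior surfaces.
These sizes make every stage's convergence checks pass with comfortable
margins while keeping a full run in the minutes range on one CPU.

Numerical details worth knowing: the stiffness matrix is SPD by coercivity
and is Cholesky-factorized (a singular factorization raises rather than
producing garbage); the spectral radius of `Â` is strictly below 1 for all
feasible parameters (verified over parameter grids); surfaces subtract the
max log density before exponentiating; degenerate inputs (zero TAC, zero
peak, empty candidate grids, mismatched sampling grids) raise informative
errors or return exact zeros as appropriate.

## Known limitations

- **Conservative bands under-cover when the posterior is tight.** The band
  propagates *parameter* uncertainty only: it is the quantile envelope of the
  deconvolved curves across posterior draws. With an informative prior and
  cohorts of complete episodes, the posterior concentrates (90% radius
  ≈ 0.05 at R = 10), the band narrows to a few percent of the signal, and the
  noise-driven deconvolution error of a held-out record (relative L2
  ≈ 15–30% at SNR 8) dominates it. In this regime the measured pointwise
  coverage of the true BrAC is far below the nominal level (the acceptance
  script reports it, ≈ 15–25% median). Wide, genuinely conservative bands
  arise only when the parameter posterior itself is broad — e.g., an
  uninformative prior or model–data misfit. A band that also propagates
  measurement noise and regularization bias would require a different
  construction (e.g., a joint hierarchical model over `q` and `u`), which is
  out of scope here.
- The deconvolved mean curve inherits the measured TAC's shape: late-episode
  TAC elevation pulls the BrAC estimate up, attenuated but visible.
- `q3`, `q4`, and `σ` are fixed, not estimated; misspecifying them biases
  `(q1, q2)` in compensating directions (only the products/ratios entering
  the filter are identified from input/output data).
- The MH sampler is adequate for this smooth 2-D posterior but makes no
  attempt at convergence diagnostics; for production use, effective sample
  size checks and multiple chains would be warranted.
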