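# Methods

## The task and its generative model

On each trial the subject sees an explicit "prior" over horizontal target
location — 100 dots on a target line, placed at the quantiles
q_i = (i − 1/2)/100 of a trial-dependent density p_prior — together with a
noisy cue.  The true target x_T is drawn uniformly from the dots; the cue
position is x_c ~ N(x_T, σ_c²), where the cue's vertical distance from the
line signals its noise level: short-distance cues are low-noise
(σ_short), long-distance cues high-noise (σ_long).  The subject points at
the believed target; a hit is a response within the cursor radius of x_T.

All positions are in standardized screen units (window width 1.0;
0.01 screen units = 3 mm of workspace, so 1 unit = 30 cm).  A session has
8 priors × 2 cue levels = 16 conditions with 36–40 repetitions, presented
in random order; a dataset is a Gaussian training session followed by a
test session from the subject's group, 32 conditions and roughly 1200
trials.  The prior's location is uniform within bounds that keep all dots
on screen, and asymmetric priors are mirrored left–right with probability
1/2.  Cues falling outside the dot range are excluded from analysis (the
trials are kept during the session to preserve the generative
statistics).  All modelling is done in relative coordinates
x̃ = ±(x − location), which is exact under translational invariance of
behavior; the likelihood is invariant under whole-trial translation by
construction (tested).

### Prior classes

* **Gaussian**: 8 single Gaussians, SDs evenly spaced on [0.04, 0.18].
* **Unimodal**: fixed total SD, varying skewness and excess kurtosis.
  Each prior is the two-Gaussian mixture that matches the four target
  moments and locally maximizes differential entropy, under a floor on the
  component SDs (preventing spiky degenerate solutions) and an explicit
  unimodality check; the moment equations at fixed mixture weight p have a
  one-dimensional solution family, so the builder scans p, solves the
  three remaining equations by least squares, filters feasible unimodal
  solutions and keeps the entropy-maximal one (entropy by grid
  quadrature).  One platykurtic member is an 11-component equal-weight
  grid mixture whose spacing and component SD solve the variance and
  kurtosis equations in closed form; one member is a plain Gaussian.
* **Bimodal**: fixed total SD, two equal-variance components with varying
  separation Δ (distance between component means, in total-SD units) and
  relative weight p.  The zero-mean constraint gives the exact solution
  μ₁ = −(1−p)Δσ, μ₂ = pΔσ, component variance σ² − p(1−p)(Δσ)²; Δ = 0
  degenerates to a single Gaussian.

### Constants

| constant | default | note |
|---|---|---|
| n_targets | 100 | dots per trial |
| σ_short, σ_long | 0.06, 0.14 | true cue-noise SDs (package defaults) |
| d_short, d_long | 6, 14 cm | cue distances; set the Weber ratio of factor S |
| success window | 0.0833 | cursor diameter (2 × 1.25 cm) |
| σ_ℓ (loss width) | 0.0324 | least-squares inverted-Gaussian fit to the square well (computed at startup) |
| test-session total SD | 0.11 | unimodal/bimodal priors (package default) |
| component-SD floor | 0.02 | unimodal entropy maximization |
| KL threshold | 0.02 nats | non-Gaussian-trial filter |

The unimodal (skewness, kurtosis) and bimodal (separation, weight) tables
are editable config entries; the shipped defaults span mildly to strongly
skewed/leptokurtic unimodal shapes and clearly bimodal to unimodal
two-Gaussian shapes.  All of the table values, the cue-noise SDs, cue
distances and the test-session SD are package choices of realistic
magnitudes, not measured quantities.

## Observer models

Every observer computes a posterior by Bayes' rule,
p(x | x_c) ∝ p_prior(x) · N(x_c; x, σ̃²), with *internal* likelihood SDs σ̃
that may mismatch the truth (three free SDs: short/long in training, short
in test; the test-session long-cue SD is tied by the training ratio).
Because priors are Gaussian mixtures, the posterior is a mixture with
component weights Z_i ∝ w_i N(x_c; μ_i, σ_i² + σ̃²) and the usual
product-of-Gaussians means and variances.

The decision stage acts on the posterior:

* **BDT** — deterministic minimization of the expected loss.  The task's
  hit-or-miss loss is approximated by an inverted Gaussian of width σ_ℓ,
  which makes the expected loss itself a (negated) Gaussian mixture in the
  action; the optimal target is the global mode of the σ_ℓ-inflated
  mixture, found by a mean-shift fixed-point iteration started from every
  component mean (tolerance 1e-10, max 1000 iterations, exact ties broken
  to the smaller coordinate).  Motor variance is not included in the
  expected loss — it shifts nothing for Gaussian posteriors and has
  negligible effect otherwise at the motor SDs considered.
* **SPK** (stochastic posterior) — target choice density ∝ posterior^κ,
  κ ≥ 1 free per session.  This is the power-function summary of a noisy
  or sample-based posterior; κ = ∞ is MAP-like, κ = 1 is matching.
* **PPM** (posterior probability matching) — the κ = 1 case, no free
  decision parameter.
* **PSA** (posterior sampling average) — the mean of K posterior draws
  (an implicit quadratic loss).  For integer K ≤ 8 the density is the
  exact multinomial expansion over component assignments; K > 8 uses the
  CLT Gaussian N(posterior mean, var/K); non-integer K linearly
  interpolates the densities at ⌊K⌋ and ⌈K⌉ (the generative sampler
  correspondingly mixes the two integer counts).
* **MV / LA** — optional Gaussian approximation applied before deciding:
  moment-matched N(mean, var), or the Laplace Gaussian at the global mode
  with variance −1/(d² log p/dx²) (typically narrower, since it sees only
  the main peak).

Optional factors, each adding one free parameter per session:

* **S** — the internal cue measurement is x_m ~ N(x_c, σ_s²), with the
  long-cue σ_s tied to the short-cue value by the distance ratio (Weber
  scaling).  The observer is not assumed aware of this noise (awareness
  only redefines σ̃).  Response probabilities marginalize x_m by
  Gauss–Hermite quadrature (order 20; exact analytically in the
  single-Gaussian path).
* **P** — noisy estimation of the prior's parameters, log-normal with
  Weber fraction η ∈ [0, 4].  Placement depends on the prior's structure:
  single-component priors perturb the width σ̂_p = σ_p e^{ηz}; two-component
  priors perturb the two mixing weights independently, equivalent to
  normal noise of SD √2·η on the log weight ratio; the 11-component
  platykurtic prior perturbs the overall scale.  Marginalized by
  Gauss–Hermite quadrature (a 1-D latent in every case).
* **L** — lapses: with probability λ per trial the choice is a draw from
  the displayed prior.  A uniform-lapse variant and a discretized-prior
  variant ("D", the prior as 100 narrow Gaussians) exist as switches.

The response is the target choice plus Gaussian motor noise (σ_motor,
shared across sessions).  For single-Gaussian priors the response density
is the closed-form normal with mean w̃·x_c, w̃ = σ_p²/(σ_p² + σ̃²), and
variance w̃²σ_s² + w̃σ̃²/κ + σ_motor²; this fully vectorized path carries
the MCMC.  Mixture priors go through grid densities (step 5e-4 screen
units, range mean ± 6 total SDs).

The basic factorial set is {BDT, SPK, PPM} × S × P × L = 24 models.
Parameter counts: BDT/PPM 4, SPK/PSA 6, +2 per S/P/L factor (e.g.
SPK-P-L has 10).

### The extended decision set and its equivalences

The decision-variant comparison enumerates
{BDT, SPK, PPM, PSA} × {none, MV, LA} × {lapse off, on} = 24 combinations
and collapses combinations that define the same model, leaving 18.  The
equivalences are derived by the package, not asserted:

1. *Algebraic*: the mean of K draws from a Gaussian is Gaussian with
   variance /K, so on MV- or LA-approximated posteriors the PSA family
   coincides exactly with the SPK power family (K ↔ κ); verified by
   density comparison at matched integer anchors on a battery of
   non-Gaussian (bimodal-session) trials.  Merges PSA-MV and PSA-LA into
   SPK-MV and SPK-LA.
2. *Behavioral*: BDT and BDT-LA are both deterministic MAP-style rules —
   the optimal action under the narrow loss applied to the Laplace
   Gaussian is the posterior mode, and the narrow-loss minimizer on the
   full posterior is the loss-smoothed mode.  Their chosen targets are of
   identical objective value (success probability) across the battery to
   ~1e-3 on average, differing only at near-tied posterior peaks, whereas
   the quadratic-loss mean rule BDT-MV differs by two orders of magnitude
   more.  Deterministic rules whose choices have equal objective value on
   the whole battery are treated as one model level.  Merges BDT-LA into
   BDT.

PPM-MV and PPM-LA are kept distinct: they are zero-decision-parameter
models (single draw from the approximated posterior), consistent with the
basic set keeping PPM separate from SPK rather than absorbing nested
special cases.

## Fitting

The likelihood is the product over non-excluded trials of the regularized
response density p̃ = p + ε, ε = φ(5) ≈ 1.487e-6 (the standard-normal
density five SDs out), which bounds any single trial's log-probability
from below and keeps outliers from dominating.

Parameter priors: log-normal on σ_motor and σ_s (log-scale log 0.01,
shape 0.5 — stand-in hyperparameters of calibration-experiment magnitude);
Uniform[0, 1] on the likelihood SDs and λ; Uniform[0, 4] on η (broad, to
avoid edge effects); and ξ = 1/κ ~ Uniform(0, 1], i.e. p(κ) ∝ κ⁻² on
κ ≥ 1 — integrable, which matters when comparing models with non-common
parameters.  K of PSA uses the same reciprocal scheme.

Sampling is coordinate-wise slice sampling with stepping-out and
shrinkage, three chains from jittered starting points, in the transformed
space (ξ for κ-like parameters, natural units otherwise).  Convergence is
monitored with the Gelman–Rubin potential scale reduction R̂ per
parameter; a multi-start MAP search (Nelder–Mead, 30 restarts) is
available as a pre-fit sanity check.  Default budget is 3 × (500 burn-in +
2000 samples); the tests use shorter chains (their R̂ is checked).

Each fit is summarized by DIC = 2·mean(D) − D(θ̂) with D = −2 log L,
effective complexity p_D = mean(D) − D(θ̂), and the robust point estimate
θ̂ = per-parameter trimmed mean (10% per side, configurable).

## Model selection

Subject-level evidence enters as log evidence = −DIC/2 (deviance-scale
approximation of the log marginal likelihood; the conversion is
configurable).  The random-effects BMS treats subjects and models as
random: variational updates u_nk ∝ exp(le_nk + ψ(α_k) − ψ(Σα)),
α = α₀ + Σ_n u_nk, with symmetric Dirichlet prior α₀ = 0.3 (a weak belief
that few models are present; the analysis driver sweeps α₀ over
0.1–3 to show robustness).  Reported are the model probabilities α/Σα
(probability that a given model generated a random subject's data) and
exceedance probabilities from 10⁵ seeded Dirichlet draws.  Factor-level
(family) probabilities sum member model probabilities, with family
exceedance computed from the same draws.  The fixed-effects alternative
(GDIC) sums DIC columns across subjects and flags differences ≥ 10 as
significant (a conservative threshold).

## Synthetic cohort

`simulate_subject` draws every response from the observer's full
generative chain — latent cue measurement, latent prior perturbation,
decision draw, lapse, motor noise — so simulation and likelihood are two
descriptions of one process; their agreement is tested by comparing the
closed-form response density with large generative simulations
(Kolmogorov–Smirnov).  Randomness is split into named streams seeded by
(seed, subject index, session index); regeneration is bit-identical.

The generator emulates the study protocol (session structure, condition
counts, discretization, flips, edge trials) but not: reaction times, the
practice block and any learning or nonstationarity, sequential trial
dependencies, or any human mismatch beyond the modelled factors.  Passing
recovery tests therefore demonstrates that the pipeline is correct and
well-calibrated on data generated by its own model class — not that the
model class describes human data.

## Nonparametric prior reconstruction

A group prior is represented as a mixture of M equally spaced Gaussian
components (means spanning the discrete-prior range; component SD = grid
spacing; default M = 30, smaller at reduced budgets) whose weights are
free.  Each subject's observer parameters are fixed (model SPK-L — no
P-factor noise, since reconstruction would confound it with the prior's
shape) and the mixing weights are slice-sampled under the pooled
likelihood with a flat prior over log-weights (one weight pinned for
identifiability, mirrored components tied for symmetric conditions,
normalization to the simplex).  Because the observer parameters are
fixed, the per-trial posterior component parameters never change during
sampling; the likelihood precomputes them and each evaluation is a small
tensor contraction.  Outputs are weight samples on the simplex, the
posterior-mean prior, and per-sample central moments; display smoothing is
cosmetic only and never applied to stored samples.

## Problem sizes in the tests and acceptance checks

The end-to-end checks run at desk scale, chosen once: parameter recovery
fits SPK-P-L (10 parameters) to 3 replicate full two-session Gaussian
datasets with 3 × (120 + 350) chains and checks pooled 95%-interval
coverage ≥ 0.9; model recovery simulates 8 subjects, fits
{SPK-P-L, BDT-P-L, PPM-P-L} on 400-trial subsamples with 3 × (100 + 300)
chains and requires the generating model to top the BMS ranking; prior
reconstruction pools 8 subjects' Gaussian test trials (≤ 44 per subject
per prior), M = 11 symmetric components, 2 × (80 + 200) chains, and
requires every recovered SD within 15% of truth.  Oracle-equivalence
checks use 100-mixture batteries, 1e-5-step grid searches and 10⁶-draw
simulations.

## Known limitations

* Non-Gaussian-prior likelihoods go through grid densities and nested
  quadratures; fitting mixture-prior sessions at full MCMC budgets is
  substantially slower than the closed-form Gaussian path.
* The unimodal prior builder's feasible region depends on the component-SD
  floor; extreme (skewness, kurtosis) pairs raise a constraint error
  rather than silently returning multimodal shapes.
* The reconstruction's flat log-weight prior is weakly informative toward
  smoother priors at small sample sizes; recovered SDs at desk scale are
  within ~10% of truth, not unbiased.
* DIC-based evidence is an approximation to the marginal likelihood;
  alternative evidence estimators (WAIC, bridge sampling) are out of
  scope.
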