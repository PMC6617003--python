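# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `stmort`, at the level of detail a maintainer needs to
judge what a passing test suite does and does not establish.

## Model and likelihood

Monthly death counts in area `i` and month `t` are
`y_it ~ Poisson(θ_it N_it)` with `N_it` the population aged ≥ 65 (a known
offset, so θ is a relative risk on the rate scale). The log relative
risk is a sum of a covariate part — intercept, linear pollutant term
(µg/m³), natural-spline smooths of temperature (°C), humidity (%) and
wind speed (m/s), and a linear static deprivation term — and, in the
joint model, a latent surface

    S_it = u_i + v_i + k_t + l_t + φ_it .

* `u_i ~ N(0, σ_u²)` iid (unstructured spatial heterogeneity).
* `v_i` intrinsic CAR (Besag): conditionally, `v_i | v_{-i}` is Normal
  with mean the neighbor average and variance `σ_v²/n_i`. The intrinsic
  prior is improper (rank I−1 on a connected graph); it is identified by
  the sum-to-zero constraint.
* `k_t ~ N(0, σ_k²)` iid; `l_t` stationary AR(1) with coefficient ρ and
  innovation SD `σ_l` (marginal variance `σ_l²/(1−ρ²)`).
* `φ_it` one of four interaction structures combining unstructured and
  structured margins: I iid; II RW1 in time per area; III an independent
  CAR field per month (default — "different spatial trends for each time
  unit"); IV RW1 ⊗ CAR. Ranks are I·T, I·(T−1), T·(I−1), (I−1)·(T−1).
  Intrinsic interaction types carry the matching margin constraints
  (type III: each month's field sums to zero over areas; type II: each
  area's path sums to zero over months; type IV: both).

Priors: coefficients N(0, 10⁶); all hyper-SDs Uniform(0, 10); ρ Uniform
on (0, 1) by default (configurable to (−1, 1)); monthly mortality
persistence is plausibly positive.

## Two-stage procedure

Stage 1 fits the covariate-only model and computes continuous residuals
`r̂_it = log(y*_it/N_it) − log θ̂_it` with `θ̂` the posterior-mean
relative-risk surface and `y* = max(y, 0.5)` (the log is undefined at
zero counts; corrected cells are flagged; the floor 0.5 is the
`zero_count_correction` config entry). The Gaussian model
`r̂_it ~ N(S_it, σ_r²)` is then fitted to the residuals, and Stage 2
refits the covariate model with the posterior mean `Ŝ` entering the
linear predictor as a fixed offset with coefficient 1. The spline terms
are re-estimated in Stage 2; only `Ŝ` is frozen. Point surfaces (`θ̂`,
`Ŝ`) are posterior means, pairing naturally with DIC's plug-in
deviance.

Rationale: in a single joint fit, a spatially structured exposure
competes with the spatial random effects and its coefficient can be
biased (spatial confounding). Freezing the spatio-temporal surface
estimated from Stage-1 residuals lets the exposure coefficient be
estimated without that competition, at the cost of ignoring uncertainty
in `Ŝ`.

## Samplers

All fits run through one Metropolis-within-Gibbs engine: independent
chains from per-chain seeds, adaptation of proposal scales during
burn-in only (Robbins–Monro on the log scale, gain 1/√t), thinning of
kept draws, and classic (split-free) Gelman–Rubin R-hat per parameter.
Defaults follow the reference protocol — 2 chains, 2500 kept draws per
chain at thinning 50 — with a burn-in of 5000; tests and the acceptance
script pass explicit shorter protocols (see "Problem sizes" below).

**Covariate models (Stages 1/2).** Coefficients update in blocks (main
effects; one block per spline) by Gaussian random walks preconditioned
with the Cholesky factor of the maximum-likelihood covariance
(`statsmodels` GLM, which also supplies initial values; chain 2 starts
at the MLE plus a 2-SD jitter). Only a scalar step size adapts, toward
acceptance 0.35. The Bayesian path is canonical; the MLE is used only
for initialization and proposal shaping.

**Gaussian residual model.** All location fields have exact Gibbs
updates. The ICAR and RW1 structure matrices are diagonalized once;
in the eigenbasis the full conditional of `v` (and of `φ`, jointly over
all cells via the Kronecker spectrum) is a product of independent
normals, and the sum-to-zero constraints are imposed exactly by zeroing
the null-eigenvector coordinates — equivalent to conditioning by
kriging. `l` uses a dense T×T Cholesky of the AR(1)-plus-likelihood
precision. Hyper-SDs update by random walk on the log scale with the
Uniform(0, 10) prior enforced by rejection (the rank of each intrinsic
structure enters the conditional's power of σ); ρ by random walk on its
support.

**Joint Poisson model.** Latent fields update by chromatic element-wise
adaptive Metropolis: a greedy graph coloring partitions the areas so
that coordinates within a class are conditionally independent given the
rest and can be proposed in parallel (time margins use odd/even
parity). Per-coordinate step sizes adapt toward acceptance 0.44 during
burn-in. Sum-to-zero recentring of `v` and of the interaction margins
happens every sweep, with the shift absorbed into β₀, `k_t` or `u_i` so
the linear predictor is unchanged; intrinsic priors are invariant to
the shifted directions, so the moves are exact.

Plain component-wise sampling of this posterior mixes too slowly to be
usable (coefficient R-hats near 2 at practical lengths) because of
likelihood-invariant ridges. Three families of extra exact moves remove
them:

1. *Level swaps*: `(x, β₀) → (x − c, β₀ + c)` for x ∈ {u, k, l}, with c
   drawn from its exact conditional (Normal with precision 1'Q1 plus
   the intercept's prior precision).
2. *Coefficient–field swaps*: the deprivation coefficient trades with
   the spatial fields along the centered-deprivation direction;
   `(v, δ) → (v − c d, δ + c)` with c again exactly conditional.
3. *Scale moves (ASIS)*: joint rescaling `(x, σ_x) → (γx, γσ_x)`; the
   prior is invariant under the map, leaving a Metropolis ratio of the
   likelihood change plus one log-γ Jacobian term.
4. *Re-splits*: the likelihood sees only u+v and k+l, so the splits are
   redrawn from their exact Gaussian conditionals each sweep (spectral
   for u/v, dense T×T for k/l).

## Splines

Natural cubic bases are built from cubic B-splines projected onto the
null space of the two boundary second-derivative constraints, with the
leading column dropped so the basis carries no intercept. A df-column
basis uses df−1 interior knots at equally spaced quantiles of the
training values and boundary knots at the observed min/max; columns are
centered on their training means. Knot placement and centering are this
package's choices (quantile knots are standard practice; centering
keeps β₀ identifiable). Definitions are frozen inside fit objects;
prediction re-evaluates the same functions, extrapolating linearly
beyond the boundary knots and flagging extrapolated points.

## Evaluation

Deviance is the full −2 log-likelihood including the log(y!) constant
(constants cancel in pD and in model differences). DIC's plug-in point
is the posterior-mean relative-risk surface. MSPE divides by the number
of predicted cells I·T; both in-sample MSPE (fitted means vs the
fitting panel) and holdout MSPE (forecast means vs a held-out year) are
reported, since either convention is defensible. Moran's I reports a
one-sided (clustering) permutation p-value and a normal-approximation
p-value from the Cliff–Ord randomization moments; which of the two a
given published analysis used is generally not stated, so both are
kept.

## Forecasting

For each retained posterior draw: spatial effects u, v are kept; the
unstructured month effect is drawn fresh from N(0, σ_k²); the AR(1)
effect continues by its recursion from the last fitted month; the
interaction extends by its own law (type III: fresh constrained CAR
field per future month; type I: iid; type II/IV: random-walk
continuation, with spatially structured increments for IV). Future
covariates and offsets must be supplied; splines evaluate with frozen
knots. Counts are drawn `y* ~ Poisson(N* θ*)`, so intervals are
equal-tailed empirical quantiles of integer predictive draws and carry
full posterior plus Poisson uncertainty (the alternative of plugging in
posterior-mean hyperparameters was rejected in favour of honest
uncertainty propagation). The two-stage fit is the canonical
forecasting base — the held-out year is predicted from the selected
Stage-2 model plus the residual-model effect draws; the joint model can
be used identically.

A practical calibration note: with T = 36 fitting months, the
month-effect hyperparameters are estimated from few effective
observations, and their posterior spread widens the predictive
intervals; measured pooled coverage of nominal 90% intervals on
synthetic replicates is ≈ 0.94 for the two-stage base and a few points
higher for the joint-model base. Within any single world, empirical
coverage is dominated by that world's realized common month shocks and
varies widely (an oracle knowing the true parameters ranges from ≈ 0.73
to ≈ 0.97 per world at these sizes); pooled multi-world coverage is the
meaningful diagnostic.

## Synthetic data

The generator draws from the joint (Model 2) law over a rook or queen
lattice. Covariate marginals default to published Korean district
summaries: PM2.5 29.4 ± 10.5 µg/m³ (PM10 preset 37.7 ± 12.1), humidity
71 ± 9 %, wind 2.9 ± 0.9 m/s, deprivation −0.1 ± 8.4, temperature with
annual mean 13.2 °C, sinusoidal seasonal amplitude 13 °C peaking in
August plus N(0, 3²) noise (range ≈ −8 to 30 °C, SD ≈ 9.6), and a
log-normal district population (median ≈ 170,000, log-SD 0.6) scaled by
an elderly fraction of 0.12 to form the ≥65 offset — the offset is
constant across months but stored I×T so annually varying populations
need no format change. True nonlinear effects default to a U-shaped
temperature curve `0.0005 (z − 18)²` (mortality minimum near 18 °C,
winter excess ≈ +40%), a mild humidity quadratic `0.0002 (w − 71)²` and
a linear wind term `0.01 q`, each centered empirically so they are
identifiable against the intercept; the true exposure coefficient is
log(1.03)/10 per µg/m³ (RR 1.03 per 10 µg/m³) and the deprivation
coefficient 0.001. Random-effect truth: σ_u = 0.1, σ_v = 0.3,
σ_k = 0.05, σ_l = 0.1 with ρ = 0.7, σ_φ = 0.1, interaction type III.
These values give death counts on the scale of the published summaries
(mean ≈ 79 per district-month) and a strong latent structure whose
fitted effective parameter count reproduces the qualitative published
pattern (joint-model pD in the hundreds, two-stage pD near the
coefficient count).

What the generator does **not** emulate: the real administrative map
(a lattice stands in), spatial or temporal correlation in the
covariates beyond the shared temperature seasonality (covariates are
independent across areas given the seasonal mean), pollution seasonal
cycles, population trends, age/sex structure, and reporting artifacts.
Passing recovery tests therefore demonstrate correctness of the
inferential machinery under the stated law, not robustness to the messiness
of real mortality surveillance data.

Constrained intrinsic fields are simulated exactly by eigendecomposing
the structure matrix and sampling the non-null coordinates with
variances σ²/λ (covariance = σ² times the Moore–Penrose pseudo-inverse),
which is the same law the samplers target.

## Problem sizes and protocols

The config default keeps the reference protocol (2 chains × 2500 kept
at thin 50). The test suite and acceptance script use scaled-down
protocols chosen once for the synthetic panel sizes they run on —
typically 2 chains, burn-in 300–600 (1200 for the joint model at
I = 100), 150–500 kept draws at thin 1–2 — and verify convergence by
R-hat rather than assuming it. Panels range from 4×3 oracle instances
to 10×10 lattices with 36–48 months.

## Degenerate inputs and numerical edges

* Isolated areas are tolerated at load time (flagged) but rejected by
  CAR-based fitting and row standardization.
* Constant pollutant or deprivation raises an identifiability error;
  constant covariates make spline knots degenerate and are rejected.
* Zero counts: deviance and residual handling as above; Poisson means
  are strictly positive by construction.
* Eigen-null detection uses a relative 1e-9 threshold; sum-to-zero
  holds to ~1e-10 in simulation output.
* Quantile ties (discrete covariates) raise an error rather than
  silently merging knots.
* R-hat on constant chains raises an error (a constant chain signals a
  broken sampler, not convergence).

## Known limitations

* Exposure effects are global: no region-specific coefficients, no
  distributed-lag structures, no age/sex stratification.
* `Ŝ` enters Stage 2 with coefficient fixed at 1 and no uncertainty
  propagation from the residual fit into the Stage-2 coefficients.
* The proper-CAR (Leroux-type) family is not implemented; the CAR prior
  is intrinsic with sum-to-zero identification.
* Chains run sequentially; no within-chain parallelism.
* Adjacency is an input (GAL-style lists); no polygon-contiguity
  derivation from shapefiles.
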