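# stmort

Bayesian spatio-temporal Poisson modelling of monthly areal mortality
counts and particulate-matter exposure, with a two-stage adjustment for
spatial confounding.

## Who this is for

Environmental epidemiologists and spatial statisticians analysing panels
of the form *I* districts × *T* months: death counts `y_it`, an elderly
population offset `N_it`, one pollutant series (PM10 or PM2.5),
meteorological covariates (temperature, humidity, wind speed) and a
static area deprivation index, together with a district contiguity
graph. The package fits, compares and forecasts from three models of
the district-month relative risk θ_it, where `y_it ~ Poisson(θ_it N_it)`:

* **Model 1** — covariates only:
  `log θ_it = β₀ + β₁X_it + S₁(Z_it) + S₂(W_it) + S₃(Q_it) + δD_i`,
  with natural cubic splines S₁–S₃ (default df 3, 2, 3) for temperature,
  humidity and wind.
* **Model 2** — the single-stage joint model adding a full latent surface
  `u_i + v_i + k_t + l_t + φ_it`: BYM spatial effects (iid `u`, intrinsic
  CAR `v`), temporal effects (iid `k`, stationary AR(1) `l`) and a
  Knorr–Held space–time interaction `φ` (types I–IV; default type III,
  an independent CAR field per month — "different spatial trends for
  each time unit").
* **Model 3** — the two-stage model: fit Model 1, decompose its
  continuous residuals `r̂_it = log(y*_it/N_it) − log θ̂_it` with the
  Gaussian model `r̂_it ~ N(S_it, σ_r²)`, `S_it = u_i+v_i+k_t+l_t+φ_it`,
  then refit the covariate model with the posterior-mean surface Ŝ as a
  fixed offset. Estimating β₁ against a frozen Ŝ avoids the spatial
  confounding that biases exposure coefficients when covariates and
  spatial random effects compete in a single fit.

Priors are deliberately vague: N(0, 10⁶) on regression coefficients and
Uniform(0, 10) on all random-effect standard deviations. Inference is
Metropolis-within-Gibbs with two chains, convergence monitored by the
Gelman–Rubin statistic. Model comparison uses DIC = D̄ + pD
(pD = D̄ − D(posterior mean)) and the mean squared prediction error
over all I·T cells; spatial structure is diagnosed with Moran's I under
binary, row-standardized and globally standardized weights. Death
counts for a held-out year are forecast from the posterior by retaining
the spatial effects, propagating the temporal effects by their own laws
and drawing Poisson counts.

Because district mortality microdata of this kind are typically not
redistributable, the package ships a first-class synthetic generator
(`stmort.synthetic`) that draws complete panels from the Model 2 law
over a contiguity lattice, with covariate marginals matching published
Korean district summaries (e.g. PM2.5 mean 29.4, SD 10.5 µg/m³;
seasonal temperature spanning ≈ −8 to 30 °C). Every claim the test
suite makes is checked against this known generative truth.

## Worked example

```python
from stmort import (MCMCSettings, ModelConfig, TrueParams, evaluate_fit,
                    lattice_graph, morans_i, simulate_covariates,
                    simulate_panel, two_stage_pipeline)

graph = lattice_graph(6, 6)                      # 36 districts
cov = simulate_covariates(36, 24, seed=7)        # 24 months of covariates
sim = simulate_panel(TrueParams(), graph, cov, seed=8)

settings = MCMCSettings(n_chains=2, burn_in=600, n_keep=400, thin=2)
config = ModelConfig(mcmc=settings)
stage1, resid_fit, stage2 = two_stage_pipeline(sim.panel, graph, config,
                                               seed=0, settings=settings)

rr, lo, hi = stage2.relative_risk_summary()      # per 10 µg/m³
print(f"RR per 10 ug/m3: {rr:.3f} (95% CrI {lo:.3f}-{hi:.3f})")
for name, fit in (("Model 1", stage1), ("Model 3", stage2)):
    rep = evaluate_fit(sim.panel.deaths, sim.panel.offset_pop,
                       fit.theta_hat, fit.samples.pooled("deviance"))
    print(f"{name}: DIC {rep.dic:.0f}  pD {rep.pD:.1f}  MSPE {rep.mspe:.1f}")
rates = (sim.panel.deaths / sim.panel.offset_pop).mean(axis=1)
m = morans_i(rates, graph, "row_standardized", n_permutations=999, seed=1)
print(f"Moran's I (row-standardized): {m.statistic:.3f}, "
      f"permutation p = {m.p_value_permutation:.3f}")
```

Output:

```
RR per 10 ug/m3: 1.032 (95% CrI 1.025-1.040)
Model 1: DIC 14438  pD 11.1  MSPE 1045.9
Model 3: DIC 6003  pD 11.6  MSPE 84.1
Moran's I (row-standardized): 0.308, permutation p = 0.006
```

The generator's true relative risk is 1.03 per 10 µg/m³, inside the
credible interval. The two-stage model (Model 3) reduces DIC and MSPE
dramatically relative to the covariates-only Model 1 while keeping an
effective parameter count (pD ≈ 12) close to the number of regression
coefficients — the latent surface enters as a fixed offset, not as free
parameters. The positive Moran's I with small permutation p confirms
the simulated mortality rates are spatially clustered.

The same workflow is available from the shell:

```bash
stmort run-all --out-dir out --rows 6 --cols 6 --months 24 --horizon 12 \
       --burn-in 600 --n-keep 400 --thin 2 --seed 7
```

which writes the panel, adjacency file, per-stage posterior summaries,
evaluation report, forecasts and a run manifest (input digests, seeds,
wall times, R-hat maxima) under `out/`.

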