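"""Posterior-predictive forecasting of death counts for held-out months.

For each retained posterior draw, the spatial effects (u, v) are kept
fixed, the unstructured monthly effect is drawn fresh from
``N(0, sigma_k^2)``, the structured monthly effect is extended by the
AR(1) recursion from its last fitted value, and the interaction field
is extended by its own law (type I: fresh iid; type II/IV: random-walk
continuation from the last fitted month; type III: a fresh constrained
ICAR field per future month).  Covariates for the horizon must be
supplied; splines are evaluated with frozen training knots (linear
extrapolation beyond the boundary is flagged).  Death counts are then
drawn ``y* ~ Poisson(N* theta*)`` so the intervals carry full posterior
plus Poisson uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import AdjacencyGraph, SpaceTimePanel
from .effects import icar_spectrum, sample_constrained_gmrf
from .models import Model2Fit, PoissonFit, ResidualFit, design_for_future


@dataclass
class ForecastResult:
    """Cellwise posterior-predictive summaries for the horizon."""

    mean: np.ndarray            # I x H predictive mean counts
    lower: np.ndarray           # I x H lower predictive bound
    upper: np.ndarray           # I x H upper predictive bound
    level: float
    n_draws: int
    horizon: int
    extrapolated: np.ndarray | None = None   # I x H spline-extrapolation mask

    def coverage(self, y_observed: np.ndarray) -> float:
        """Fraction of observed cells inside [lower, upper]."""
        y = np.asarray(y_observed, dtype=float)
        return float(np.mean((y >= self.lower) & (y <= self.upper)))


def _effect_draws(fit, effects):
    """Pooled per-draw effect arrays from either a residual fit or the
    joint-model fit itself."""
    src = effects.samples if isinstance(effects, ResidualFit) else effects.samples
    pooled = {k: src.pooled(k) for k in
              ("u", "v", "k", "l", "phi_last", "sigma_k", "sigma_l",
               "sigma_phi", "rho")}
    return pooled


def forecast(fit: "PoissonFit | Model2Fit",
             effects: "ResidualFit | Model2Fit",
             future_panel: SpaceTimePanel,
             graph: AdjacencyGraph | None = None,
             horizon: int | None = None,
             level: float = 0.95,
             max_draws: int = 2000,
             seed: int | np.random.Generator = 0) -> ForecastResult:
    """Posterior-predictive death counts for the future panel's months.

    ``fit`` supplies the coefficient draws and frozen splines (a Stage-2
    fit or the joint fit); ``effects`` supplies random-effect draws and
    their hyperparameters (the residual fit, or the same joint fit).
    ``future_panel`` carries the future covariates and offsets (its
    deaths are ignored).  ``graph`` defaults to the one stored in
    ``effects``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H = future_panel.n_months if horizon is None else int(horizon)
    I = future_panel.n_areas
    if H == 0:
        empty = np.zeros((I, 0))
        return ForecastResult(mean=empty, lower=empty, upper=empty,
                              level=level, n_draws=0, horizon=0,
                              extrapolated=np.zeros((I, 0), dtype=bool))
    if H > future_panel.n_months:
        raise ValueError("horizon exceeds the months in the future panel")
    fut = future_panel if H == future_panel.n_months else \
        future_panel.subset_months(range(H))
    graph = graph if graph is not None else getattr(effects, "graph", None)
    if graph is None:
        raise ValueError("an adjacency graph is required for the forecast")

    Xf, extrap = design_for_future(fit, fut.pollutant, fut.temperature,
                                   fut.humidity, fut.wind, fut.deprivation)
    coef = fit.samples.pooled("beta0")[:, None]
    order = ["beta1", "delta"]
    cols = [fit.samples.pooled(n)[:, None] for n in order]
    spl = [fit.samples.pooled(f"spl_{c}") for c in
           ("temperature", "humidity", "wind")]
    coef_draws = np.concatenate([coef] + cols + spl, axis=1)   # D x p

    eff = _effect_draws(fit, effects)
    D_total = coef_draws.shape[0]
    D_eff = eff["u"].shape[0]
    n_draws = min(D_total, D_eff, max_draws)
    idx = np.linspace(0, min(D_total, D_eff) - 1, n_draws).astype(int)

    itype = (effects.interaction_type if isinstance(effects, ResidualFit)
             else effects.config.interaction_type)
    sspec = icar_spectrum(graph) if itype in ("III", "IV") else None

    logN = np.log(fut.offset_pop.astype(float))
    draws = np.empty((n_draws, I, H), dtype=np.int64)
    ex_mask = extrap.reshape(I, H)
    for j, d in enumerate(idx):
        lin = (Xf @ coef_draws[d]).reshape(I, H)
        sk, sl, sphi, rho = (eff["sigma_k"][d], eff["sigma_l"][d],
                             eff["sigma_phi"][d], eff["rho"][d])
        k_star = rng.normal(0.0, sk, H)
        l_star = np.empty(H)
        prev = eff["l"][d][-1]
        for h in range(H):
            prev = rho * prev + rng.normal(0.0, sl)
            l_star[h] = prev
        if itype == "I":
            phi_star = rng.normal(0.0, sphi, (I, H))
        elif itype in ("II", "IV"):
            # random-walk continuation; type IV increments are spatially
            # structured (constrained ICAR) rather than iid
            phi_star = np.empty((I, H))
            prev_col = eff["phi_last"][d]
            for h in range(H):
                step = (rng.normal(0.0, sphi, I) if itype == "II"
                        else sample_constrained_gmrf(sspec, sphi, rng))
                prev_col = prev_col + step
                phi_star[:, h] = prev_col
        else:
            phi_star = sample_constrained_gmrf(sspec, sphi, rng, size=H).T
        eta = (lin + (eff["u"][d] + eff["v"][d])[:, None]
               + (k_star + l_star)[None, :] + phi_star)
        draws[j] = rng.poisson(np.exp(eta + logN))

    alpha = (1.0 - level) / 2
    # endpoints are actual integer draws (equal-tailed empirical quantiles)
    return ForecastResult(
        mean=draws.mean(axis=0),
        lower=np.quantile(draws, alpha, axis=0, method="inverted_cdf"),
        upper=np.quantile(draws, 1 - alpha, axis=0, method="higher"),
        level=level, n_draws=n_draws, horizon=H, extrapolated=ex_mask)


def naive_forecast(train_panel: SpaceTimePanel, horizon: int) -> np.ndarray:
    """Per-area mean of the training counts, repeated over the horizon
    (baseline the model forecast should beat when temporal structure is
    real)."""
    m = train_panel.deaths.mean(axis=1)
    return np.repeat(m[:, None], horizon, axis=1)
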