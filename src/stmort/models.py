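"""The three mortality models and the two-stage fitting pipeline.

Stage 1 ("Model 1") is a Poisson log-linear covariate model

    y_it ~ Poisson(theta_it N_it),
    log theta_it = b0 + b1 X_it + S1(Z_it) + S2(W_it) + S3(Q_it) + d D_i,

with natural-cubic-spline smooths of temperature, humidity and wind.
Its fitted relative risks define continuous residuals
``r_it = log(y*_it / N_it) - log(theta^_it)`` which are then decomposed
by a Gaussian spatio-temporal model ``r_it ~ N(S_it, sigma_r^2)`` with
``S_it = u_i + v_i + k_t + l_t + phi_it`` (BYM space, iid + AR(1) time,
Knorr-Held interaction).  Stage 2 ("Model 3") refits the covariate
model with the posterior-mean surface S^ as a fixed offset, breaking
the competition between the exposure and the spatial field (spatial
confounding).  "Model 2" is the corresponding single-stage joint model.

All fits use the Metropolis-within-Gibbs engine: coefficient blocks are
adaptive random-walk proposals preconditioned with the maximum-
likelihood covariance; Gaussian-model location fields are exact Gibbs
in the eigenbasis of their structure matrices; the joint Poisson model
updates fields by chromatic element-wise adaptive Metropolis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg, special

from .core_data import AdjacencyGraph, MCMCSettings, ModelConfig, SpaceTimePanel
from .effects import (GMRFSpectrum, ar1_log_density, ar1_precision,
                      icar_precision, icar_spectrum, rw1_precision,
                      rw1_spectrum)
from .mcmc import Block, PosteriorSamples, gelman_rubin, run
from .splines import SplineBasisDef, apply_basis, fit_basis

COVARIATE_SPLINES = ("temperature", "humidity", "wind")


class IdentifiabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Flattened (C-order, area-major) design for the covariate model."""

    X: np.ndarray
    names: list
    blocks: dict
    spline_defs: dict
    pollutant_mean: float
    deprivation_mean: float
    I: int
    T: int


def build_design(panel: SpaceTimePanel, config: ModelConfig,
                 spline_defs: Mapping[str, SplineBasisDef] | None = None) -> DesignInfo:
    """Design matrix with intercept, centered pollutant and deprivation,
    and centered spline columns for the three meteorological covariates.

    Passing ``spline_defs`` reuses frozen knots/centering (prediction)."""
    I, T = panel.shape
    pol = panel.pollutant.ravel()
    dep = np.repeat(panel.deprivation, T)
    if np.ptp(pol) == 0:
        raise IdentifiabilityError("pollutant series is constant")
    if np.ptp(panel.deprivation) == 0:
        raise IdentifiabilityError("deprivation index is constant")
    pol_mean, dep_mean = float(pol.mean()), float(dep.mean())

    cols = [np.ones(I * T), pol - pol_mean, dep - dep_mean]
    names = ["beta0", "beta1", "delta"]
    blocks = {"main": np.array([0, 1, 2])}
    defs = {}
    dfs = dict(zip(COVARIATE_SPLINES, config.spline_df))
    for cov in COVARIATE_SPLINES:
        x = getattr(panel, cov).ravel()
        if spline_defs is None:
            sdef, mat = fit_basis(x, dfs[cov])
        else:
            sdef = spline_defs[cov]
            mat, _ = apply_basis(sdef, x)
        defs[cov] = sdef
        start = len(names)
        for j in range(mat.shape[1]):
            names.append(f"spl_{cov}[{j}]")
        blocks[f"spl_{cov}"] = np.arange(start, start + mat.shape[1])
        cols.append(mat)
    X = np.column_stack([np.column_stack(cols[:3])] + cols[3:])
    return DesignInfo(X=X, names=names, blocks=blocks, spline_defs=defs,
                      pollutant_mean=pol_mean, deprivation_mean=dep_mean,
                      I=I, T=T)


def design_for_future(info_or_fit, pollutant, temperature, humidity, wind,
                      deprivation) -> tuple[np.ndarray, np.ndarray]:
    """Re-evaluate a fitted design at future covariates (frozen splines).

    Returns the flattened design matrix and a boolean extrapolation mask
    (any spline evaluated beyond its training boundary knots)."""
    src = info_or_fit
    I, H = np.asarray(pollutant).shape
    pol = np.asarray(pollutant, dtype=float).ravel()
    dep = np.repeat(np.asarray(deprivation, dtype=float), H)
    cols = [np.ones(I * H), pol - src.pollutant_mean, dep - src.deprivation_mean]
    extrap = np.zeros(I * H, dtype=bool)
    covs = {"temperature": temperature, "humidity": humidity, "wind": wind}
    for cov in COVARIATE_SPLINES:
        mat, mask = apply_basis(src.spline_defs[cov],
                                np.asarray(covs[cov], dtype=float).ravel())
        cols.append(mat)
        extrap |= mask
    return np.column_stack(cols), extrap


# ---------------------------------------------------------------------------
# shared blocks
# ---------------------------------------------------------------------------

class CoefBlock(Block):
    """Joint adaptive random-walk update of a coefficient sub-block of a
    Poisson log-linear model, preconditioned by the MLE covariance.

    Maintains ``state['lin'] = X @ coef`` and ``state['mu']`` (Poisson
    means) incrementally.
    """

    def __init__(self, name, idx, X, y_flat, prior_var, chol,
                 target_accept=0.35):
        self.name = name
        self.idx = np.asarray(idx)
        self.Xb = X[:, self.idx]
        self.yX = y_flat @ self.Xb
        self.prior_var = prior_var
        self.chol = chol
        self.step = 1.0
        self.target_accept = target_accept
        self._adapt_count = 0
        self._accepted = 0
        self._proposed = 0

    def initial_logpost(self, state):
        mu = state["mu"]
        return float(state["y_flat"] @ np.log(mu) - mu.sum())

    def update(self, state, rng, adapt):
        coef = state["coef"]
        d = self.step * (self.chol @ rng.standard_normal(self.idx.size))
        dlin = self.Xb @ d
        mu = state["mu"]
        new_mu = mu * np.exp(dlin)
        cur = coef[self.idx]
        dprior = -(np.sum((cur + d) ** 2) - np.sum(cur ** 2)) / (2 * self.prior_var)
        dll = self.yX @ d - (new_mu.sum() - mu.sum()) + dprior
        accepted = np.log(rng.uniform()) < dll
        if accepted:
            coef[self.idx] = cur + d
            state["lin"] = state["lin"] + dlin
            state["mu"] = new_mu
        if adapt:
            self._adapt_count += 1
            gain = 1.0 / np.sqrt(self._adapt_count)
            self.step *= np.exp(gain * (float(accepted) - self.target_accept))
        else:
            self._proposed += 1
            self._accepted += int(accepted)

    @property
    def acceptance_rate(self):
        return None if self._proposed == 0 else self._accepted / self._proposed


class LogScaleRWBlock(Block):
    """Random-walk Metropolis on log(sigma) with a Uniform(0, upper)
    prior on sigma enforced by rejection.

    ``logpost(state, sigma)`` returns the log of the conditional density
    of the model given sigma (prior factor excluded; it is flat).
    """

    def __init__(self, name, key, logpost, upper, step0=0.3, target_accept=0.44):
        self.name = name
        self.key = key
        self.logpost = logpost
        self.upper = upper
        self.step = step0
        self.target_accept = target_accept
        self._adapt_count = 0
        self._accepted = 0
        self._proposed = 0

    def initial_logpost(self, state):
        return float(self.logpost(state, state[self.key]))

    def update(self, state, rng, adapt):
        cur = state[self.key]
        prop = cur * np.exp(self.step * rng.standard_normal())
        accepted = False
        if 0 < prop < self.upper:
            # Jacobian of the log transform: extra log(prop/cur)
            dll = (self.logpost(state, prop) - self.logpost(state, cur)
                   + np.log(prop) - np.log(cur))
            if np.log(rng.uniform()) < dll:
                state[self.key] = prop
                accepted = True
        if adapt:
            self._adapt_count += 1
            gain = 1.0 / np.sqrt(self._adapt_count)
            self.step *= np.exp(gain * (float(accepted) - self.target_accept))
        else:
            self._proposed += 1
            self._accepted += int(accepted)

    @property
    def acceptance_rate(self):
        return None if self._proposed == 0 else self._accepted / self._proposed


# ---------------------------------------------------------------------------
# Stage 1 / Stage 2 covariate model
# ---------------------------------------------------------------------------

def _mle_fit(y_flat, X, offset_log):
    """Poisson GLM maximum-likelihood point and covariance (initialization
    and proposal preconditioning; the Bayesian path is canonical)."""
    import statsmodels.api as sm
    try:
        res = sm.GLM(y_flat, X, family=sm.families.Poisson(),
                     offset=offset_log).fit(maxiter=200)
        cov = np.asarray(res.cov_params())
        return np.asarray(res.params), cov
    except Exception:
        p = X.shape[1]
        return np.zeros(p), np.eye(p) * 1e-4


class _PoissonCovariateModel:
    """Engine model for Models 1 and 3 (coefficients only)."""

    def __init__(self, panel, config, design, offset_extra=None):
        self.design = design
        self.config = config
        self.y_flat = panel.deaths.ravel().astype(float)
        self.logN = np.log(panel.offset_pop.ravel().astype(float))
        self.offset = self.logN + (0.0 if offset_extra is None
                                   else np.asarray(offset_extra, dtype=float).ravel())
        self.extra = self.offset - self.logN
        self.coef_hat, self.coef_cov = _mle_fit(self.y_flat, design.X, self.offset)
        self._gammaln_y = float(special.gammaln(self.y_flat + 1).sum())
        self.theta_sum = np.zeros(self.y_flat.size)
        self.theta_count = 0

    def init_state(self, chain, rng):
        coef = self.coef_hat.copy()
        if chain > 0:
            sd = np.sqrt(np.clip(np.diag(self.coef_cov), 1e-12, None))
            coef = coef + 2.0 * sd * rng.standard_normal(coef.size)
        lin = self.design.X @ coef
        return {"coef": coef, "lin": lin,
                "mu": np.exp(lin + self.offset), "y_flat": self.y_flat}

    def make_blocks(self, state):
        blocks = []
        for name, idx in self.design.blocks.items():
            sub = self.coef_cov[np.ix_(idx, idx)]
            try:
                chol = np.linalg.cholesky(sub) * 2.4 / np.sqrt(idx.size)
            except np.linalg.LinAlgError:
                chol = np.eye(idx.size) * 0.01
            blocks.append(CoefBlock(name, idx, self.design.X, self.y_flat,
                                    self.config.coef_prior_variance, chol,
                                    self.config.mcmc.target_accept))
        return blocks

    def deviance(self, state):
        mu = state["mu"]
        ll = self.y_flat @ np.log(mu) - mu.sum() - self._gammaln_y
        return -2.0 * ll

    def track(self, state):
        coef = state["coef"]
        out = {"beta0": coef[0], "beta1": coef[1], "delta": coef[2],
               "deviance": self.deviance(state)}
        for name, idx in self.design.blocks.items():
            if name != "main":
                out[name] = coef[idx]
        return out

    def on_keep(self, state, chain):
        # theta = mu / N includes any fixed offset surface S^ so the
        # plug-in deviance sees the full fitted relative risk
        self.theta_sum += np.exp(state["lin"] + self.extra)
        self.theta_count += 1


@dataclass
class PoissonFit:
    """Posterior of a covariate model (Stage 1 or Stage 2)."""

    samples: PosteriorSamples
    theta_hat: np.ndarray                 # I x T posterior-mean relative risk
    spline_defs: dict
    pollutant_mean: float
    deprivation_mean: float
    config: ModelConfig
    offset_surface: np.ndarray | None = None
    convergence_warnings: list = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        r = gelman_rubin({k: self.samples.params[k]
                          for k in ("beta0", "beta1", "delta")})
        return float(max(np.max(np.atleast_1d(v)) for v in r.values()))

    def relative_risk_summary(self, delta_x: float = 10.0):
        return relative_risk(self.samples.pooled("beta1"), delta_x)


Stage1Fit = PoissonFit
Stage2Fit = PoissonFit


def _fit_covariate_model(panel, config, seed, settings, offset_extra):
    design = build_design(panel, config)
    model = _PoissonCovariateModel(panel, config, design,
                                   offset_extra=offset_extra)
    settings = settings or config.mcmc
    samples = run(model, settings, seed=seed)
    theta_hat = (model.theta_sum / model.theta_count).reshape(panel.shape)
    fit = PoissonFit(samples=samples, theta_hat=theta_hat,
                     spline_defs=design.spline_defs,
                     pollutant_mean=design.pollutant_mean,
                     deprivation_mean=design.deprivation_mean,
                     config=config,
                     offset_surface=(None if offset_extra is None
                                     else np.asarray(offset_extra)))
    rhats = gelman_rubin({k: samples.params[k]
                          for k in ("beta0", "beta1", "delta")})
    for k, v in rhats.items():
        if np.max(np.atleast_1d(v)) > 1.1:
            fit.convergence_warnings.append(
                f"R-hat {np.max(np.atleast_1d(v)):.3f} > 1.1 for {k}")
    return fit


def fit_model1(panel: SpaceTimePanel, config: ModelConfig | None = None,
               seed: int = 0, settings: MCMCSettings | None = None) -> Stage1Fit:
    """Stage-1 covariate-only Poisson model."""
    return _fit_covariate_model(panel, config or ModelConfig(), seed,
                                settings, offset_extra=None)


def fit_model3(panel: SpaceTimePanel, S_hat: np.ndarray,
               config: ModelConfig | None = None, seed: int = 0,
               settings: MCMCSettings | None = None) -> Stage2Fit:
    """Stage-2 model: the covariate model with the estimated residual
    surface S^ entering the linear predictor as a fixed offset."""
    S_hat = np.asarray(S_hat, dtype=float)
    if S_hat.shape != panel.shape:
        raise ValueError(f"S_hat shape {S_hat.shape} != panel shape {panel.shape}")
    return _fit_covariate_model(panel, config or ModelConfig(), seed,
                                settings, offset_extra=S_hat)


def relative_risk(beta1_samples: np.ndarray,
                  delta_x: float = 10.0) -> tuple[float, float, float]:
    """Posterior mean and 95% credible interval of the relative risk per
    ``delta_x`` unit increase of exposure: RR = exp(delta_x * beta1)."""
    b = np.asarray(beta1_samples, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty coefficient sample")
    rr = np.exp(delta_x * b)
    return (float(rr.mean()), float(np.quantile(rr, 0.025)),
            float(np.quantile(rr, 0.975)))


# ---------------------------------------------------------------------------
# residuals and the Gaussian spatio-temporal model
# ---------------------------------------------------------------------------

def compute_residuals(panel: SpaceTimePanel, theta_hat: np.ndarray,
                      zero_count_correction: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous residuals r_it = log(y*_it / N_it) - log(theta^_it).

    Zero counts are floored at ``zero_count_correction`` (the log is
    undefined at 0); the returned mask flags corrected cells."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    if np.any(theta_hat <= 0):
        raise ValueError("theta_hat must be positive")
    mask = panel.deaths == 0
    y_star = np.where(mask, zero_count_correction, panel.deaths).astype(float)
    resid = np.log(y_star / panel.offset_pop) - np.log(theta_hat)
    return resid, mask


def _identity_spectrum(n: int) -> GMRFSpectrum:
    return GMRFSpectrum(np.ones(n), np.eye(n))


def _interaction_spectra(itype, graph, T):
    I = graph.n_areas
    if itype == "I":
        return _identity_spectrum(I), _identity_spectrum(T)
    if itype == "II":
        return _identity_spectrum(I), rw1_spectrum(T)
    if itype == "III":
        return icar_spectrum(graph), _identity_spectrum(T)
    if itype == "IV":
        return icar_spectrum(graph), rw1_spectrum(T)
    raise ValueError(f"unknown interaction type {itype!r}")


def _interaction_quad(itype, phi, Qs, Qt):
    """phi' Q phi for the interaction structure (unit scale)."""
    if itype == "I":
        return float(np.sum(phi ** 2))
    if itype == "II":
        return float(np.sum(phi * (phi @ Qt.T)))
    if itype == "III":
        return float(np.sum(phi * (Qs @ phi)))
    return float(np.sum(phi * (Qs @ phi @ Qt.T)))


class _ResidualModel:
    """Exact-Gibbs engine model for r_it ~ N(S_it, sigma_r^2)."""

    def __init__(self, resid, graph, config, fixed=None):
        self.r = np.asarray(resid, dtype=float)
        self.I, self.T = self.r.shape
        self.graph = graph
        self.config = config
        self.fixed = dict(fixed or {})
        self.itype = config.interaction_type
        if not graph.is_connected():
            raise ValueError("residual model requires a connected adjacency graph")
        self.sp = icar_spectrum(graph)
        self.phi_s, self.phi_t = _interaction_spectra(self.itype, graph, self.T)
        self.Qs = icar_precision(graph).toarray()
        self.Qt = rw1_precision(self.T).toarray()
        self.S_sum = np.zeros_like(self.r)
        self.S_count = 0

    # -- helpers -----------------------------------------------------------
    def surface(self, st):
        return (st["u"] + st["v"])[:, None] + (st["k"] + st["l"])[None, :] + st["phi"]

    def init_state(self, chain, rng):
        st = {"u": np.zeros(self.I), "v": np.zeros(self.I),
              "k": np.zeros(self.T), "l": np.zeros(self.T),
              "phi": np.zeros((self.I, self.T))}
        base = {"sigma_u": 0.1, "sigma_v": 0.1, "sigma_k": 0.05,
                "sigma_l": 0.05, "sigma_phi": 0.05, "rho": 0.5,
                "sigma_r": max(0.05, float(self.r.std()))}
        for key, val in base.items():
            if key in self.fixed:
                st[key] = float(self.fixed[key])
            else:
                jitter = float(np.exp(0.5 * rng.standard_normal())) if chain > 0 else 1.0
                st[key] = min(val * jitter, 0.9 * self.config.hyper_sd_upper) \
                    if key != "rho" else min(0.9, val * jitter)
        return st

    # -- exact conditionals ------------------------------------------------
    def _upd_u(self, st, rng):
        R = self.r - self.surface(st) + st["u"][:, None]
        prec = self.T / st["sigma_r"] ** 2 + 1.0 / st["sigma_u"] ** 2
        mean = R.sum(axis=1) / st["sigma_r"] ** 2 / prec
        return {"u": mean + rng.standard_normal(self.I) / np.sqrt(prec)}

    def _upd_v(self, st, rng):
        R = self.r - self.surface(st) + st["v"][:, None]
        b = R.sum(axis=1) / st["sigma_r"] ** 2
        lam = self.sp.eigvals / st["sigma_v"] ** 2 + self.T / st["sigma_r"] ** 2
        bt = self.sp.eigvecs.T @ b
        coord = bt / lam + rng.standard_normal(self.I) / np.sqrt(lam)
        coord[self.sp.null_mask] = 0.0          # sum-to-zero constraint
        return {"v": self.sp.eigvecs @ coord}

    def _upd_k(self, st, rng):
        R = self.r - self.surface(st) + st["k"][None, :]
        prec = self.I / st["sigma_r"] ** 2 + 1.0 / st["sigma_k"] ** 2
        mean = R.sum(axis=0) / st["sigma_r"] ** 2 / prec
        return {"k": mean + rng.standard_normal(self.T) / np.sqrt(prec)}

    def _upd_l(self, st, rng):
        R = self.r - self.surface(st) + st["l"][None, :]
        P = ar1_precision(self.T, st["rho"], st["sigma_l"])
        P[np.diag_indices(self.T)] += self.I / st["sigma_r"] ** 2
        b = R.sum(axis=0) / st["sigma_r"] ** 2
        cf = linalg.cho_factor(P, lower=True)
        mean = linalg.cho_solve(cf, b)
        z = linalg.solve_triangular(cf[0], rng.standard_normal(self.T),
                                    lower=True, trans="T")
        return {"l": mean + z}

    def _upd_phi(self, st, rng):
        R = self.r - self.surface(st) + st["phi"]
        B = self.phi_s.eigvecs.T @ (R / st["sigma_r"] ** 2) @ self.phi_t.eigvecs
        lam = (np.outer(self.phi_s.eigvals, self.phi_t.eigvals)
               / st["sigma_phi"] ** 2 + 1.0 / st["sigma_r"] ** 2)
        coord = B / lam + rng.standard_normal((self.I, self.T)) / np.sqrt(lam)
        null = self.phi_s.null_mask[:, None] | self.phi_t.null_mask[None, :]
        coord[null] = 0.0
        return {"phi": self.phi_s.eigvecs @ coord @ self.phi_t.eigvecs.T}

    # -- hyper log-conditionals (flat priors; rank-deficiency aware) -------
    def _lp_sigma_u(self, st, s):
        return -self.I * np.log(s) - np.sum(st["u"] ** 2) / (2 * s ** 2)

    def _lp_sigma_v(self, st, s):
        quad = st["v"] @ (self.Qs @ st["v"])
        return -(self.I - 1) * np.log(s) - quad / (2 * s ** 2)

    def _lp_sigma_k(self, st, s):
        return -self.T * np.log(s) - np.sum(st["k"] ** 2) / (2 * s ** 2)

    def _lp_sigma_l(self, st, s):
        return ar1_log_density(st["l"], st["rho"], s)

    def _lp_sigma_phi(self, st, s):
        quad = _interaction_quad(self.itype, st["phi"], self.Qs, self.Qt)
        ranks = {"I": self.I * self.T, "II": self.I * (self.T - 1),
                 "III": self.T * (self.I - 1),
                 "IV": (self.I - 1) * (self.T - 1)}
        return -ranks[self.itype] * np.log(s) - quad / (2 * s ** 2)

    def _lp_sigma_r(self, st, s):
        quad = np.sum((self.r - self.surface(st)) ** 2)
        return -self.r.size * np.log(s) - quad / (2 * s ** 2)

    def make_blocks(self, state):
        from .mcmc import GibbsBlock, RandomWalkBlock
        blocks = [GibbsBlock("u", self._upd_u), GibbsBlock("v", self._upd_v),
                  GibbsBlock("k", self._upd_k), GibbsBlock("l", self._upd_l),
                  GibbsBlock("phi", self._upd_phi)]
        upper = self.config.hyper_sd_upper
        for key in ("sigma_u", "sigma_v", "sigma_k", "sigma_l",
                    "sigma_phi", "sigma_r"):
            if key not in self.fixed:
                blocks.append(LogScaleRWBlock(
                    key, key, getattr(self, f"_lp_{key}"), upper))
        if "rho" not in self.fixed:
            lo, hi = self.config.ar1_rho_bounds
            blocks.append(RandomWalkBlock(
                "rho", "rho",
                lambda st: ar1_log_density(st["l"], st["rho"], st["sigma_l"]),
                step0=0.1, target_accept=0.44,
                support=lambda r: lo < r < hi))
        return blocks

    def track(self, st):
        return {"sigma_u": st["sigma_u"], "sigma_v": st["sigma_v"],
                "sigma_k": st["sigma_k"], "sigma_l": st["sigma_l"],
                "sigma_phi": st["sigma_phi"], "rho": st["rho"],
                "sigma_r": st["sigma_r"], "u": st["u"], "v": st["v"],
                "k": st["k"], "l": st["l"], "phi_last": st["phi"][:, -1]}

    def on_keep(self, st, chain):
        self.S_sum += self.surface(st)
        self.S_count += 1


@dataclass
class ResidualFit:
    """Posterior of the Gaussian residual decomposition."""

    samples: PosteriorSamples
    S_hat: np.ndarray
    interaction_type: str
    config: ModelConfig
    graph: AdjacencyGraph


def fit_residual_model(residuals: np.ndarray, graph: AdjacencyGraph,
                       config: ModelConfig | None = None, seed: int = 0,
                       settings: MCMCSettings | None = None,
                       fixed_hypers: Mapping[str, float] | None = None
                       ) -> ResidualFit:
    """Fit the spatio-temporal decomposition of the Stage-1 residuals.

    ``fixed_hypers`` pins any of sigma_u/v/k/l/phi/r and rho (their
    update blocks are skipped), e.g. for oracle comparisons."""
    config = config or ModelConfig()
    resid = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(resid)):
        raise ValueError("residual matrix contains non-finite values")
    model = _ResidualModel(resid, graph, config, fixed=fixed_hypers)
    samples = run(model, settings or config.mcmc, seed=seed)
    S_hat = model.S_sum / model.S_count
    return ResidualFit(samples=samples, S_hat=S_hat,
                       interaction_type=config.interaction_type,
                       config=config, graph=graph)


def two_stage_pipeline(panel: SpaceTimePanel, graph: AdjacencyGraph,
                       config: ModelConfig | None = None, seed: int = 0,
                       settings: MCMCSettings | None = None):
    """Model 1 -> residuals -> residual model -> Model 3.

    Returns (stage1, residual_fit, stage2)."""
    config = config or ModelConfig()
    stage1 = fit_model1(panel, config, seed=seed, settings=settings)
    resid, _ = compute_residuals(panel, stage1.theta_hat,
                                 config.zero_count_correction)
    rfit = fit_residual_model(resid, graph, config, seed=seed + 1,
                              settings=settings)
    stage2 = fit_model3(panel, rfit.S_hat, config, seed=seed + 2,
                        settings=settings)
    return stage1, rfit, stage2


# ---------------------------------------------------------------------------
# Model 2: single-stage joint model
# ---------------------------------------------------------------------------

class _FieldMHBlock(Block):
    """Chromatic element-wise adaptive random-walk update of one latent
    field of the joint Poisson model.

    Coordinates within a color class are conditionally independent given
    the rest of the state, so they are proposed and accepted in
    parallel; per-coordinate step sizes adapt during burn-in only.
    """

    def __init__(self, name, model, step0=0.1, target_accept=0.44):
        self.name = name
        self.model = model
        self.target_accept = target_accept
        self.step0 = step0
        self.steps = None
        self._adapt_count = 0
        self._accepted = 0.0
        self._proposed = 0

    def _init_steps(self, shape):
        if self.steps is None:
            self.steps = np.full(shape, self.step0)

    def _mh(self, dll, rng, adapt):
        """Element-wise accept/reject; returns the accept mask and the
        multiplicative step-adaptation factors (None outside burn-in)."""
        accept = np.log(rng.uniform(size=dll.shape)) < dll
        factors = None
        if adapt:
            self._adapt_count += 1
            gain = 1.0 / np.sqrt(self._adapt_count)
            factors = np.exp(gain * (accept.astype(float) - self.target_accept))
        else:
            self._proposed += accept.size
            self._accepted += accept.sum()
        return accept, factors

    @property
    def acceptance_rate(self):
        return None if self._proposed == 0 else float(self._accepted / self._proposed)


class _AreaIidBlock(_FieldMHBlock):
    """u_i: iid Normal(0, sigma_u^2); rows conditionally independent."""

    def update(self, st, rng, adapt):
        m = self.model
        self._init_steps(m.I)
        MU = st["mu"].reshape(m.I, m.T)
        u = st["u"]
        du = self.steps * rng.standard_normal(m.I)
        dll = (du * m.y_rowsum - MU.sum(axis=1) * np.expm1(du)
               - ((u + du) ** 2 - u ** 2) / (2 * st["sigma_u"] ** 2))
        acc, fac = self._mh(dll, rng, adapt)
        if fac is not None:
            self.steps *= fac
        u[acc] += du[acc]
        MU[acc, :] *= np.exp(du[acc])[:, None]


class _CARBlock(_FieldMHBlock):
    """v_i: intrinsic CAR; updated by color class, then recentred with
    the shift absorbed into the intercept (likelihood-invariant)."""

    def update(self, st, rng, adapt):
        m = self.model
        self._init_steps(m.I)
        MU = st["mu"].reshape(m.I, m.T)
        v = st["v"]
        sig2 = st["sigma_v"] ** 2
        for cls in m.colors:
            nb_mean = (m.A[cls] @ v) / m.n_nbrs[cls]
            dv = self.steps[cls] * rng.standard_normal(cls.size)
            cur = v[cls]
            dll = (dv * m.y_rowsum[cls] - MU[cls].sum(axis=1) * np.expm1(dv)
                   - m.n_nbrs[cls] / (2 * sig2)
                   * ((cur + dv - nb_mean) ** 2 - (cur - nb_mean) ** 2))
            acc, fac = self._mh(dll, rng, adapt)
            if fac is not None:
                self.steps[cls] = self.steps[cls] * fac
            sel = cls[acc]
            v[sel] += dv[acc]
            MU[sel, :] *= np.exp(dv[acc])[:, None]
        shift = v.mean()
        v -= shift
        st["coef"][0] += shift
        st["lin"] = st["lin"] + shift


class _TimeIidBlock(_FieldMHBlock):
    """k_t: iid Normal(0, sigma_k^2); columns conditionally independent."""

    def update(self, st, rng, adapt):
        m = self.model
        self._init_steps(m.T)
        MU = st["mu"].reshape(m.I, m.T)
        k = st["k"]
        dk = self.steps * rng.standard_normal(m.T)
        dll = (dk * m.y_colsum - MU.sum(axis=0) * np.expm1(dk)
               - ((k + dk) ** 2 - k ** 2) / (2 * st["sigma_k"] ** 2))
        acc, fac = self._mh(dll, rng, adapt)
        if fac is not None:
            self.steps *= fac
        k[acc] += dk[acc]
        MU[:, acc] *= np.exp(dk[acc])[None, :]


class _AR1Block(_FieldMHBlock):
    """l_t: stationary AR(1); odd/even months are conditionally
    independent given each other (tridiagonal precision)."""

    def update(self, st, rng, adapt):
        m = self.model
        self._init_steps(m.T)
        MU = st["mu"].reshape(m.I, m.T)
        l, rho, sig = st["l"], st["rho"], st["sigma_l"]
        Q = ar1_precision(m.T, rho, sig)
        prec = np.diag(Q).copy()
        for cls in (np.arange(0, m.T, 2), np.arange(1, m.T, 2)):
            # conditional mean from the tridiagonal precision
            off = Q[cls][:, :] @ l - prec[cls] * l[cls]
            mean = -off / prec[cls]
            dl = self.steps[cls] * rng.standard_normal(cls.size)
            cur = l[cls]
            dll = (dl * m.y_colsum[cls] - MU[:, cls].sum(axis=0) * np.expm1(dl)
                   - prec[cls] / 2
                   * ((cur + dl - mean) ** 2 - (cur - mean) ** 2))
            acc, fac = self._mh(dll, rng, adapt)
            if fac is not None:
                self.steps[cls] = self.steps[cls] * fac
            sel = cls[acc]
            l[sel] += dl[acc]
            MU[:, sel] *= np.exp(dl[acc])[None, :]


class _InteractionBlock(_FieldMHBlock):
    """phi_it under one of the four interaction priors, with chromatic
    parallel updates and margin recentring absorbed into k (and u)."""

    def update(self, st, rng, adapt):
        m = self.model
        self._init_steps((m.I, m.T))
        MU = st["mu"].reshape(m.I, m.T)
        phi = st["phi"]
        sig2 = st["sigma_phi"] ** 2
        itype = m.config.interaction_type
        if itype == "I":
            classes = [(np.arange(m.I), np.arange(m.T))]
        elif itype == "II":
            classes = [(np.arange(m.I), np.arange(0, m.T, 2)),
                       (np.arange(m.I), np.arange(1, m.T, 2))]
        elif itype == "III":
            classes = [(cls, np.arange(m.T)) for cls in m.colors]
        else:
            classes = [(cls, par) for cls in m.colors
                       for par in (np.arange(0, m.T, 2), np.arange(1, m.T, 2))]
        for rows, cols in classes:
            sub = np.ix_(rows, cols)
            cur = phi[sub]
            if itype == "I":
                prec = np.full(cur.shape, 1.0 / sig2)
                mean = np.zeros(cur.shape)
            elif itype == "II":
                Qt = m.Qt
                prec = np.diag(Qt)[cols][None, :] / sig2
                off = (phi @ Qt.T)[sub] / sig2 - prec * cur
                mean = -off / prec
            elif itype == "III":
                prec = m.n_nbrs[rows][:, None] / sig2
                mean = (m.A[rows] @ phi)[:, cols] / m.n_nbrs[rows][:, None]
            else:
                prec = np.outer(np.diag(m.Qs)[rows], np.diag(m.Qt)[cols]) / sig2
                off = (m.Qs @ phi @ m.Qt.T)[sub] / sig2 - prec * cur
                mean = -off / prec
            dphi = self.steps[sub] * rng.standard_normal(cur.shape)
            dll = (dphi * m.y[sub] - MU[sub] * np.expm1(dphi)
                   - prec / 2 * ((cur + dphi - mean) ** 2 - (cur - mean) ** 2))
            acc, fac = self._mh(dll, rng, adapt)
            if fac is not None:
                self.steps[sub] = self.steps[sub] * fac
            newphi = np.where(acc, cur + dphi, cur)
            MU[sub] = MU[sub] * np.exp(newphi - cur)
            phi[sub] = newphi
        # recentre the intrinsic null directions; shifts absorbed so the
        # linear predictor (hence mu) is unchanged
        if itype in ("III", "IV"):
            col = phi.mean(axis=0)
            phi -= col[None, :]
            st["k"] += col
        if itype in ("II", "IV"):
            row = phi.mean(axis=1)
            phi -= row[:, None]
            st["u"] += row


class _LevelSwapBlock(Block):
    """Exact Gibbs move along the likelihood-invariant ridge between the
    intercept and the free level of a random-effect vector.

    The transformation (x, b0) -> (x - c, b0 + c) leaves the linear
    predictor unchanged; c is drawn from its conditional density along
    that direction, which under the effect's Gaussian prior (and the
    essentially flat intercept prior) is Normal with precision 1'Q1.
    This removes the slow random-walk mixing of b0 against the levels
    of u, k and l.
    """

    def __init__(self, name, key, prec_fn, intercept_prior_var=1e6):
        self.name = name
        self.key = key
        self.prec_fn = prec_fn    # state -> (precision matrix or scalar)
        self.b0_prec = 1.0 / intercept_prior_var

    def update(self, st, rng, adapt):
        x = st[self.key]
        q = self.prec_fn(st)
        if np.ndim(q) == 0:       # iid prior: Q = (1/s^2) I
            denom = q * x.size
            num = q * x.sum()
        else:
            q1 = q.sum(axis=1)
            denom = q1.sum()
            num = q1 @ x
        denom += self.b0_prec
        num -= self.b0_prec * st["coef"][0]
        c = num / denom + rng.standard_normal() / np.sqrt(denom)
        st[self.key] = x - c
        st["coef"][0] += c
        st["lin"] = st["lin"] + c


class _FieldScaleBlock(Block):
    """Joint rescaling move (x, sigma) -> (gamma x, gamma sigma).

    A non-centered ("ancillarity") move that breaks the slow mixing of a
    variance parameter against its own field: the prior density is
    scale-invariant under the joint map, so the Metropolis ratio reduces
    to the likelihood change plus a single log-gamma Jacobian term.
    """

    def __init__(self, name, key, sigma_key, model, step0=0.1,
                 target_accept=0.44):
        self.name = name
        self.key = key
        self.sigma_key = sigma_key
        self.model = model
        self.step = step0
        self.target_accept = target_accept
        self._adapt_count = 0
        self._accepted = 0
        self._proposed = 0

    def _delta_eta(self, st, gamma):
        m = self.model
        x = st[self.key]
        if self.key in ("u", "v"):
            return (gamma - 1) * x[:, None] * np.ones((1, m.T))
        if self.key in ("k", "l"):
            return (gamma - 1) * np.ones((m.I, 1)) * x[None, :]
        return (gamma - 1) * x

    def update(self, st, rng, adapt):
        m = self.model
        gamma = float(np.exp(self.step * rng.standard_normal()))
        new_sigma = st[self.sigma_key] * gamma
        accepted = False
        if 0 < new_sigma < m.config.hyper_sd_upper:
            deta = self._delta_eta(st, gamma)
            MU = st["mu"].reshape(m.I, m.T)
            dll = float(np.sum(m.y * deta - MU * np.expm1(deta)))
            # prior scale-invariance leaves a single Jacobian log-gamma
            if np.log(rng.uniform()) < dll + np.log(gamma):
                st[self.key] = st[self.key] * gamma
                st[self.sigma_key] = new_sigma
                st["mu"] = (MU * np.exp(deta)).ravel()
                accepted = True
        if adapt:
            self._adapt_count += 1
            gain = 1.0 / np.sqrt(self._adapt_count)
            self.step *= np.exp(gain * (float(accepted) - self.target_accept))
        else:
            self._proposed += 1
            self._accepted += int(accepted)

    @property
    def acceptance_rate(self):
        return None if self._proposed == 0 else self._accepted / self._proposed


class _ResplitBlock(Block):
    """Exact Gibbs redraw of a two-component decomposition given its sum.

    The likelihood sees only s = x1 + x2, so x1 | s, hypers is Gaussian
    with precision Q1 + Q2 and canonical mean Q2 s; redrawing it every
    sweep decouples the two variance parameters from a frozen split.
    For the spatial pair (u iid, v ICAR) the ICAR null coordinate of v
    is pinned to zero (sum-to-zero), which fixes the corresponding
    coordinate of x1 = u at the value carried by s.
    """

    def __init__(self, name, keys, model):
        self.name = name
        self.keys = keys          # ("u", "v") or ("k", "l")
        self.model = model

    def update(self, st, rng, adapt):
        m = self.model
        k1, k2 = self.keys
        s = st[k1] + st[k2]
        if k1 == "u":
            sp = m.sp
            st_coords = sp.eigvecs.T @ s
            prec = 1.0 / st["sigma_u"] ** 2 + sp.eigvals / st["sigma_v"] ** 2
            bmean = (sp.eigvals / st["sigma_v"] ** 2) * st_coords / prec
            u_coords = bmean + rng.standard_normal(m.I) / np.sqrt(prec)
            # v's null coordinate is 0, so u carries s there exactly
            u_coords[sp.null_mask] = st_coords[sp.null_mask]
            u = sp.eigvecs @ u_coords
            st[k1], st[k2] = u, s - u
        else:
            Q2 = ar1_precision(m.T, st["rho"], st["sigma_l"])
            P = Q2.copy()
            P[np.diag_indices(m.T)] += 1.0 / st["sigma_k"] ** 2
            cf = linalg.cho_factor(P, lower=True)
            mean = linalg.cho_solve(cf, Q2 @ s)
            z = linalg.solve_triangular(cf[0], rng.standard_normal(m.T),
                                        lower=True, trans="T")
            k = mean + z
            st[k1], st[k2] = k, s - k


class _CoefFieldSwapBlock(Block):
    """Exact Gibbs move along the ridge between a regression coefficient
    of a purely spatial covariate and a spatial random-effect vector.

    For a static area covariate d (centered), the transformation
    (x, coef_j) -> (x - c d, coef_j + c) leaves the linear predictor
    unchanged; c is drawn from its conditional under the effect's prior,
    Normal with precision d'Qd (plus the coefficient's prior precision).
    """

    def __init__(self, name, key, coef_index, direction, prec_fn,
                 coef_prior_var=1e6):
        self.name = name
        self.key = key
        self.j = coef_index
        self.d = np.asarray(direction, dtype=float)
        self.prec_fn = prec_fn
        self.coef_prec = 1.0 / coef_prior_var

    def update(self, st, rng, adapt):
        x = st[self.key]
        q = self.prec_fn(st)
        if np.ndim(q) == 0:
            denom = q * self.d @ self.d
            num = q * self.d @ x
        else:
            qd = q @ self.d
            denom = self.d @ qd
            num = qd @ x
        denom += self.coef_prec
        num -= self.coef_prec * st["coef"][self.j]
        c = num / denom + rng.standard_normal() / np.sqrt(denom)
        st[self.key] = x - c * self.d
        st["coef"][self.j] += c
        # the covariate design column is the centered d repeated over
        # months, so lin shifts by c * d cellwise and mu is unchanged
        st["lin"] = st["lin"] + c * np.repeat(self.d, st["phi"].shape[1])


class _JointModel:
    """Engine model for the single-stage spatio-temporal Poisson model."""

    def __init__(self, panel, graph, config):
        if not graph.is_connected():
            raise ValueError("joint model requires a connected adjacency graph")
        self.config = config
        self.graph = graph
        self.design = build_design(panel, config)
        self.I, self.T = panel.shape
        self.y = panel.deaths.astype(float)
        self.y_flat = self.y.ravel()
        self.y_rowsum = self.y.sum(axis=1)
        self.y_colsum = self.y.sum(axis=0)
        self.logN = np.log(panel.offset_pop.ravel().astype(float))
        self.dep_centered = panel.deprivation - panel.deprivation.mean()
        self.A = graph.adjacency_matrix().toarray()
        self.n_nbrs = graph.n_neighbors.astype(float)
        if np.any(self.n_nbrs == 0):
            raise ValueError("joint model requires every area to have a neighbor")
        self.colors = graph.coloring()
        self.sp = icar_spectrum(graph)
        self.Qs = icar_precision(graph).toarray()
        self.Qt = rw1_precision(self.T).toarray()
        self.coef_hat, self.coef_cov = _mle_fit(self.y_flat, self.design.X,
                                                self.logN)
        self._gammaln_y = float(special.gammaln(self.y_flat + 1).sum())
        self.theta_sum = np.zeros(self.y_flat.size)
        self.theta_count = 0

    def init_state(self, chain, rng):
        coef = self.coef_hat.copy()
        if chain > 0:
            sd = np.sqrt(np.clip(np.diag(self.coef_cov), 1e-12, None))
            coef = coef + 2.0 * sd * rng.standard_normal(coef.size)
        lin = self.design.X @ coef
        st = {"coef": coef, "lin": lin, "y_flat": self.y_flat,
              "u": np.zeros(self.I), "v": np.zeros(self.I),
              "k": np.zeros(self.T), "l": np.zeros(self.T),
              "phi": np.zeros((self.I, self.T))}
        for key, val in (("sigma_u", 0.1), ("sigma_v", 0.1), ("sigma_k", 0.05),
                         ("sigma_l", 0.05), ("sigma_phi", 0.05), ("rho", 0.5)):
            jitter = float(np.exp(0.5 * rng.standard_normal())) if chain > 0 else 1.0
            st[key] = (min(val * jitter, 0.9 * self.config.hyper_sd_upper)
                       if key != "rho" else min(0.9, val * jitter))
        st["mu"] = np.exp(lin + self.logN + self._effects_flat(st))
        return st

    def _effects_flat(self, st):
        eff = ((st["u"] + st["v"])[:, None] + (st["k"] + st["l"])[None, :]
               + st["phi"])
        return eff.ravel()

    # hyper conditionals reuse the residual-model algebra
    def _lp_sigma_u(self, st, s):
        return -self.I * np.log(s) - np.sum(st["u"] ** 2) / (2 * s ** 2)

    def _lp_sigma_v(self, st, s):
        return (-(self.I - 1) * np.log(s)
                - st["v"] @ (self.Qs @ st["v"]) / (2 * s ** 2))

    def _lp_sigma_k(self, st, s):
        return -self.T * np.log(s) - np.sum(st["k"] ** 2) / (2 * s ** 2)

    def _lp_sigma_l(self, st, s):
        return ar1_log_density(st["l"], st["rho"], s)

    def _lp_sigma_phi(self, st, s):
        itype = self.config.interaction_type
        quad = _interaction_quad(itype, st["phi"], self.Qs, self.Qt)
        ranks = {"I": self.I * self.T, "II": self.I * (self.T - 1),
                 "III": self.T * (self.I - 1),
                 "IV": (self.I - 1) * (self.T - 1)}
        return -ranks[itype] * np.log(s) - quad / (2 * s ** 2)

    def make_blocks(self, state):
        from .mcmc import RandomWalkBlock
        blocks = []
        for name, idx in self.design.blocks.items():
            sub = self.coef_cov[np.ix_(idx, idx)]
            try:
                chol = np.linalg.cholesky(sub) * 2.4 / np.sqrt(idx.size)
            except np.linalg.LinAlgError:
                chol = np.eye(idx.size) * 0.01
            blocks.append(CoefBlock(name, idx, self.design.X, self.y_flat,
                                    self.config.coef_prior_variance, chol,
                                    self.config.mcmc.target_accept))
        blocks += [_AreaIidBlock("u", self), _CARBlock("v", self),
                   _TimeIidBlock("k", self), _AR1Block("l", self),
                   _InteractionBlock("phi", self),
                   _LevelSwapBlock("swap_u", "u",
                                   lambda st: 1.0 / st["sigma_u"] ** 2),
                   _LevelSwapBlock("swap_k", "k",
                                   lambda st: 1.0 / st["sigma_k"] ** 2),
                   _LevelSwapBlock("swap_l", "l",
                                   lambda st: ar1_precision(
                                       self.T, st["rho"], st["sigma_l"])),
                   _CoefFieldSwapBlock("swap_delta_u", "u", 2,
                                       self.dep_centered,
                                       lambda st: 1.0 / st["sigma_u"] ** 2,
                                       self.config.coef_prior_variance),
                   _CoefFieldSwapBlock("swap_delta_v", "v", 2,
                                       self.dep_centered,
                                       lambda st: self.Qs / st["sigma_v"] ** 2,
                                       self.config.coef_prior_variance)]
        upper = self.config.hyper_sd_upper
        for key in ("sigma_u", "sigma_v", "sigma_k", "sigma_l", "sigma_phi"):
            blocks.append(LogScaleRWBlock(key, key, getattr(self, f"_lp_{key}"),
                                          upper))
        for field_key, sig in (("u", "sigma_u"), ("v", "sigma_v"),
                               ("k", "sigma_k"), ("l", "sigma_l"),
                               ("phi", "sigma_phi")):
            blocks.append(_FieldScaleBlock(f"scale_{field_key}", field_key,
                                           sig, self))
        blocks += [_ResplitBlock("resplit_uv", ("u", "v"), self),
                   _ResplitBlock("resplit_kl", ("k", "l"), self)]
        lo, hi = self.config.ar1_rho_bounds
        blocks.append(RandomWalkBlock(
            "rho", "rho",
            lambda st: ar1_log_density(st["l"], st["rho"], st["sigma_l"]),
            step0=0.1, target_accept=0.44, support=lambda r: lo < r < hi))
        return blocks

    def deviance(self, state):
        mu = state["mu"]
        return -2.0 * (self.y_flat @ np.log(mu) - mu.sum() - self._gammaln_y)

    def track(self, st):
        coef = st["coef"]
        out = {"beta0": coef[0], "beta1": coef[1], "delta": coef[2],
               "deviance": self.deviance(st),
               "sigma_u": st["sigma_u"], "sigma_v": st["sigma_v"],
               "sigma_k": st["sigma_k"], "sigma_l": st["sigma_l"],
               "sigma_phi": st["sigma_phi"], "rho": st["rho"],
               "u": st["u"].copy(), "v": st["v"].copy(),
               "k": st["k"].copy(), "l": st["l"].copy(),
               "phi_last": st["phi"][:, -1].copy()}
        for name, idx in self.design.blocks.items():
            if name != "main":
                out[name] = coef[idx]
        return out

    def on_keep(self, st, chain):
        self.theta_sum += st["mu"] / np.exp(self.logN)
        self.theta_count += 1


@dataclass
class Model2Fit:
    """Posterior of the joint single-stage model."""

    samples: PosteriorSamples
    theta_hat: np.ndarray
    spline_defs: dict
    pollutant_mean: float
    deprivation_mean: float
    config: ModelConfig
    graph: AdjacencyGraph
    convergence_warnings: list = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        r = gelman_rubin({k: self.samples.params[k]
                          for k in ("beta0", "beta1", "delta")})
        return float(max(np.max(np.atleast_1d(v)) for v in r.values()))

    def relative_risk_summary(self, delta_x: float = 10.0):
        return relative_risk(self.samples.pooled("beta1"), delta_x)


def fit_model2(panel: SpaceTimePanel, graph: AdjacencyGraph,
               config: ModelConfig | None = None, seed: int = 0,
               settings: MCMCSettings | None = None) -> Model2Fit:
    """Single-stage joint fit of covariates and all random effects."""
    config = config or ModelConfig()
    model = _JointModel(panel, graph, config)
    samples = run(model, settings or config.mcmc, seed=seed)
    theta_hat = (model.theta_sum / model.theta_count).reshape(panel.shape)
    fit = Model2Fit(samples=samples, theta_hat=theta_hat,
                    spline_defs=model.design.spline_defs,
                    pollutant_mean=model.design.pollutant_mean,
                    deprivation_mean=model.design.deprivation_mean,
                    config=config, graph=graph)
    rhats = gelman_rubin({k: samples.params[k]
                          for k in ("beta0", "beta1", "delta")})
    for k, v in rhats.items():
        if np.max(np.atleast_1d(v)) > 1.1:
            fit.convergence_warnings.append(
                f"R-hat {np.max(np.atleast_1d(v)):.3f} > 1.1 for {k}")
    return fit
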