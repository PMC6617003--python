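import numpy as np
import pytest

from stmort import (MCMCSettings, ModelConfig, TrueParams, compute_residuals,
                    fit_model1, fit_model2, fit_model3, fit_residual_model,
                    lattice_graph, relative_risk, simulate_covariates,
                    simulate_panel)
from stmort.core_data import SpaceTimePanel
from stmort.models import IdentifiabilityError, build_design


def covariate_only_truth(beta1=0.003):
    """Generative law matching the Stage-1 model (no random effects)."""
    return TrueParams(beta1=beta1, sigma_u=0, sigma_v=0, sigma_k=0,
                      sigma_l=0, sigma_phi=0, rho=0)


class TestComputeResiduals:
    def make_panel(self, y):
        I, T = y.shape
        rng = np.random.default_rng(0)
        return SpaceTimePanel(
            area_ids=list(range(I)), month_index=list(range(T)),
            deaths=y, offset_pop=np.full((I, T), 1000),
            pollutant=rng.normal(30, 5, (I, T)),
            temperature=rng.normal(13, 5, (I, T)),
            humidity=rng.uniform(50, 90, (I, T)),
            wind=rng.uniform(1, 5, (I, T)),
            deprivation=rng.normal(0, 5, I))

    def test_exact_rate_gives_zero(self):
        panel = self.make_panel(np.full((2, 2), 10))
        r, mask = compute_residuals(panel, np.full((2, 2), 0.01))
        np.testing.assert_allclose(r, 0.0, atol=1e-14)
        assert not mask.any()

    def test_double_rate_gives_log2(self):
        panel = self.make_panel(np.full((1, 1), 20))
        r, _ = compute_residuals(panel, np.full((1, 1), 0.01))
        assert r[0, 0] == pytest.approx(np.log(2))

    def test_zero_count_correction_and_mask(self):
        panel = self.make_panel(np.zeros((1, 1), dtype=int))
        r, mask = compute_residuals(panel, np.full((1, 1), 0.01),
                                    zero_count_correction=0.5)
        assert r[0, 0] == pytest.approx(np.log(0.0005) - np.log(0.01))
        assert mask[0, 0]

    def test_nonpositive_theta_rejected(self):
        panel = self.make_panel(np.full((1, 1), 5))
        with pytest.raises(ValueError):
            compute_residuals(panel, np.zeros((1, 1)))


class TestRelativeRisk:
    def test_zero_coefficient_gives_unit_rr(self):
        mean, lo, hi = relative_risk(np.zeros(100))
        assert mean == lo == hi == 1.0

    def test_table_inversion(self):
        b = np.full(50, np.log(1.028) / 10)
        mean, lo, hi = relative_risk(b)
        assert mean == pytest.approx(1.028)

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0.002, 0.0004, 500)
        base = relative_risk(b)
        shifted = relative_risk(b + 0.001)
        assert all(s > r for s, r in zip(shifted, base))


@pytest.fixture(scope="module")
def model1_data():
    g = lattice_graph(10, 10)
    cov = simulate_covariates(100, 24, seed=21)
    return simulate_panel(covariate_only_truth(), g, cov, seed=22)


@pytest.fixture(scope="module")
def model1_fit(model1_data):
    settings = MCMCSettings(n_chains=2, burn_in=400, n_keep=300, thin=2)
    return fit_model1(model1_data.panel, ModelConfig(), seed=1,
                      settings=settings)


class TestStage1:
    def test_beta1_recovered(self, model1_fit):
        b = model1_fit.samples.pooled("beta1")
        assert abs(b.mean() - 0.003) < 2 * b.std()

    def test_theta_hat_tracks_truth(self, model1_data, model1_fit):
        rel = np.abs(model1_fit.theta_hat / model1_data.theta - 1)
        assert np.median(rel) < 0.05

    def test_seed_determinism(self, model1_data):
        settings = MCMCSettings(n_chains=2, burn_in=50, n_keep=30, thin=1)
        a = fit_model1(model1_data.panel, ModelConfig(), seed=9,
                       settings=settings)
        b = fit_model1(model1_data.panel, ModelConfig(), seed=9,
                       settings=settings)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)

    def test_constant_pollutant_rejected(self, model1_data):
        panel = model1_data.panel
        bad = SpaceTimePanel(**{**panel.__dict__,
                                "pollutant": np.full(panel.shape, 30.0)})
        with pytest.raises(IdentifiabilityError):
            build_design(bad, ModelConfig())


class TestResidualModel:
    def test_zero_residuals_give_flat_surface(self, grid44, fast_settings):
        resid = np.zeros((16, 12))
        fit = fit_residual_model(resid, grid44,
                                 ModelConfig(mcmc=fast_settings), seed=2,
                                 settings=fast_settings)
        assert np.abs(fit.S_hat).max() < 0.02

    def test_sigma_r_recovered(self):
        """Residuals generated from the Gaussian decomposition recover
        the observation SD."""
        g = lattice_graph(10, 10)
        rng = np.random.default_rng(31)
        from stmort.effects import (sample_ar1, sample_constrained_icar,
                                    sample_interaction)
        I, T = 100, 24
        S = (rng.normal(0, 0.1, I)[:, None]
             + sample_constrained_icar(g, 0.3, rng)[:, None]
             + rng.normal(0, 0.05, T)[None, :]
             + sample_ar1(T, 0.7, 0.1, rng)[None, :]
             + sample_interaction("III", g, T, 0.1, rng))
        resid = S + rng.normal(0, 0.2, (I, T))
        settings = MCMCSettings(n_chains=2, burn_in=400, n_keep=300, thin=1)
        fit = fit_residual_model(resid, g, ModelConfig(), seed=3,
                                 settings=settings)
        sr = fit.samples.pooled("sigma_r").mean()
        assert 0.15 < sr < 0.25
        # and the fitted surface tracks the true one
        assert np.corrcoef(fit.S_hat.ravel(), S.ravel())[0, 1] > 0.8

    def test_disconnected_graph_rejected(self):
        from stmort.core_data import AdjacencyGraph
        g = AdjacencyGraph(4, [[1], [0], [3], [2]])
        with pytest.raises(ValueError, match="connected"):
            fit_residual_model(np.zeros((4, 3)), g, ModelConfig(), seed=0)


class TestStage2:
    def test_zero_offset_surface_reduces_to_model1(self, small_sim,
                                                   fast_settings):
        cfg = ModelConfig(mcmc=fast_settings)
        f1 = fit_model1(small_sim.panel, cfg, seed=5, settings=fast_settings)
        f3 = fit_model3(small_sim.panel, np.zeros(small_sim.panel.shape), cfg,
                        seed=5, settings=fast_settings)
        np.testing.assert_allclose(f3.samples.pooled("beta1"),
                                   f1.samples.pooled("beta1"), atol=1e-12)

    def test_shape_mismatch_rejected(self, small_sim):
        with pytest.raises(ValueError, match="shape"):
            fit_model3(small_sim.panel, np.zeros((2, 2)), ModelConfig())

    def test_seed_determinism(self, small_sim, fast_settings):
        cfg = ModelConfig(mcmc=fast_settings)
        S = np.full(small_sim.panel.shape, 0.1)
        a = fit_model3(small_sim.panel, S, cfg, seed=8, settings=fast_settings)
        b = fit_model3(small_sim.panel, S, cfg, seed=8, settings=fast_settings)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
        assert a.relative_risk_summary() == b.relative_risk_summary()


class TestJointModel:
    def test_degenerate_variance_limit_matches_model1(self):
        """On data without random effects the joint model's beta1
        posterior agrees with the covariate-only model."""
        g = lattice_graph(5, 5)
        cov = simulate_covariates(25, 18, seed=41)
        sim = simulate_panel(covariate_only_truth(), g, cov, seed=42)
        settings = MCMCSettings(n_chains=2, burn_in=500, n_keep=400, thin=1)
        cfg = ModelConfig(mcmc=settings)
        f1 = fit_model1(sim.panel, cfg, seed=6, settings=settings)
        f2 = fit_model2(sim.panel, g, cfg, seed=6, settings=settings)
        b1, b2 = f1.samples.pooled("beta1"), f2.samples.pooled("beta1")
        mcse = np.sqrt(b1.std() ** 2 / 50 + b2.std() ** 2 / 50)
        assert abs(b1.mean() - b2.mean()) < max(4 * mcse, 0.3 * b1.std())

    def test_seed_determinism(self, small_sim, grid44, fast_settings):
        cfg = ModelConfig(mcmc=fast_settings)
        a = fit_model2(small_sim.panel, grid44, cfg, seed=4,
                       settings=fast_settings)
        b = fit_model2(small_sim.panel, grid44, cfg, seed=4,
                       settings=fast_settings)
        np.testing.assert_array_equal(a.samples.params["beta1"],
                                      b.samples.params["beta1"])
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)

    def test_sum_to_zero_identification(self, small_sim, grid44,
                                        fast_settings):
        """v and the type-III interaction column sums are recentred to
        zero every sweep."""
        cfg = ModelConfig(mcmc=fast_settings)
        fit = fit_model2(small_sim.panel, grid44, cfg, seed=4,
                         settings=fast_settings)
        v_draws = fit.samples.pooled("v")
        assert np.abs(v_draws.sum(axis=1)).max() < 1e-8
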