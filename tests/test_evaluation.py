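import numpy as np
import pytest
from scipy import stats

from stmort import (calibration_pairs, dic_from_samples, lattice_graph,
                    morans_i, mspe, pearson_residuals, poisson_deviance,
                    weight_matrix)
from stmort.core_data import AdjacencyGraph
from stmort.evaluation import EvalReport, evaluate_fit


class TestPoissonDeviance:
    def test_zero_count_unit_mean(self):
        # y=0, mu=1: loglik = -1, deviance = 2
        assert poisson_deviance(np.array([0]), np.array([1.0]),
                                np.array([1.0])) == pytest.approx(2.0)

    def test_additivity(self):
        y = np.array([3.0, 7.0])
        theta = np.array([0.01, 0.02])
        N = np.array([100.0, 200.0])
        total = poisson_deviance(y, theta, N)
        parts = sum(poisson_deviance(y[[i]], theta[[i]], N[[i]])
                    for i in range(2))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_matches_logpmf_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(8, (5, 4))
        theta = rng.uniform(0.005, 0.02, (5, 4))
        N = rng.integers(200, 900, (5, 4)).astype(float)
        want = -2 * stats.poisson.logpmf(y, theta * N).sum()
        assert poisson_deviance(y, theta, N) == pytest.approx(want, abs=1e-10)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            poisson_deviance(np.array([1]), np.array([0.0]), np.array([10.0]))


class TestDIC:
    def test_constant_deviance(self):
        frag = dic_from_samples(np.full(100, 42.0), 42.0)
        assert frag["pD"] == 0.0 and frag["dic"] == 42.0

    @pytest.mark.parametrize("dbar,dmean,pD,dic", [
        (72_690.0, 72_679.0, 11.0, 72_701.0),
        (63_597.0, 63_049.0, 548.0, 64_145.0),
        (63_098.0, 63_088.0, 10.0, 63_108.0),
    ])
    def test_reported_row_arithmetic(self, dbar, dmean, pD, dic):
        frag = dic_from_samples(np.full(10, dbar), dmean)
        assert frag["pD"] == pytest.approx(pD)
        assert frag["dic"] == pytest.approx(dic)

    def test_internal_identities_enforced(self):
        with pytest.raises(ValueError):
            EvalReport(mspe=0, dbar=10, d_at_mean=8, pD=3, dic=13, n_cells=1)
        rep = EvalReport(mspe=0.0, dbar=10.0, d_at_mean=8.0, pD=2.0, dic=12.0,
                         n_cells=4)
        assert rep.dic == rep.dbar + rep.pD
        assert rep.pD == rep.dbar - rep.d_at_mean

    def test_evaluate_fit_identities(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(20, (4, 5))
        N = np.full((4, 5), 1000.0)
        theta = np.full((4, 5), 0.02)
        dev = rng.normal(100, 3, 200)
        rep = evaluate_fit(y, N, theta, dev)
        assert abs(rep.dic - (rep.dbar + rep.pD)) < 1e-9
        assert abs(rep.pD - (rep.dbar - rep.d_at_mean)) < 1e-9


class TestMSPE:
    def test_examples(self):
        assert mspe(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert mspe(np.array([1.0, 2.0]), np.array([2.0, 4.0])) == 2.5

    def test_reshape_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(6, 4))
        yhat = rng.normal(size=(6, 4))
        assert mspe(y, yhat) == pytest.approx(mspe(y.ravel(), yhat.ravel()))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mspe(np.zeros(3), np.zeros(4))


class TestPearson:
    def test_exact_values(self):
        np.testing.assert_allclose(
            pearson_residuals(np.array([4.0]), np.array([1.0])), [3.0])
        np.testing.assert_allclose(
            pearson_residuals(np.array([5.0]), np.array([5.0])), [0.0])

    def test_unit_variance_under_true_model(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(50, 150, 4000)
        y = rng.poisson(mu)
        r = pearson_residuals(y, mu)
        assert 0.9 < r.std() < 1.1


def brute_force_moran(x, W):
    n = len(x)
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / W.sum() * num / den


class TestMoran:
    @pytest.mark.parametrize("scheme", ["binary", "row_standardized",
                                        "globally_standardized"])
    def test_matches_double_loop_oracle_on_path(self, scheme):
        g = AdjacencyGraph(4, [[1], [0, 2], [1, 3], [2]])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = morans_i(x, g, scheme, n_permutations=49, seed=0)
        W = weight_matrix(g, scheme)
        assert res.statistic == pytest.approx(brute_force_moran(x, W),
                                              abs=1e-12)
        assert res.expectation == pytest.approx(-1 / 3)

    def test_checkerboard_is_negative(self):
        g = lattice_graph(2, 2)
        x = np.array([1.0, -1.0, -1.0, 1.0])
        res = morans_i(x, g, "row_standardized", n_permutations=49, seed=0)
        W = weight_matrix(g, "row_standardized")
        assert res.statistic < 0
        assert res.statistic == pytest.approx(brute_force_moran(x, W),
                                              abs=1e-12)

    def test_null_permutation_p_uniform(self):
        """Permutation p-values are approximately uniform under spatial
        randomness (KS over 200 simulated nulls)."""
        g = lattice_graph(4, 4)
        rng = np.random.default_rng(3)
        pvals = []
        for i in range(200):
            x = rng.normal(size=16)
            res = morans_i(x, g, "row_standardized", n_permutations=199,
                           seed=int(rng.integers(2**31)))
            pvals.append(res.p_value_permutation)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_normal_and_permutation_p_agree_roughly(self):
        g = lattice_graph(5, 5)
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        x[:13] += np.linspace(0, 1.5, 13)  # mild structure
        res = morans_i(x, g, "row_standardized", n_permutations=1999, seed=9)
        assert abs(res.p_value_normal - res.p_value_permutation) < 0.1

    def test_constant_input_rejected(self):
        g = lattice_graph(2, 2)
        with pytest.raises(ValueError):
            morans_i(np.ones(4), g, "binary")


class TestCalibration:
    def test_perfect_predictions_slope_one(self):
        y = np.arange(1.0, 13.0).reshape(3, 4)
        table, slope = calibration_pairs(y, y)
        assert slope == pytest.approx(1.0)
        assert len(table) == 12

    def test_round_trip_through_csv(self, tmp_path):
        rng = np.random.default_rng(5)
        y = rng.poisson(30, 20).astype(float)
        yhat = y + rng.normal(0, 2, 20)
        table, _ = calibration_pairs(y, yhat)
        path = tmp_path / "pairs.csv"
        table.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["observed"], y)
        np.testing.assert_allclose(back["estimated"], yhat)
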