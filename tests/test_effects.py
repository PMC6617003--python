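import numpy as np
import pytest
from scipy import stats

from stmort import (ar1_log_density, icar_full_conditional,
                    interaction_precision, lattice_graph,
                    sample_constrained_icar)
from stmort.core_data import AdjacencyGraph
from stmort.effects import (ar1_precision, icar_precision, rw1_precision,
                            sample_ar1, sample_interaction)


class TestICARConditional:
    def test_two_neighbors(self):
        g = AdjacencyGraph(3, [[1], [0, 2], [1]])
        v = np.array([1.0, 0.0, 3.0])
        mean, sd = icar_full_conditional(v, 1, g, sigma_v=1.0)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1 / np.sqrt(2))

    def test_single_neighbor(self):
        g = AdjacencyGraph(2, [[1], [0]])
        mean, sd = icar_full_conditional(np.array([0.0, 5.0]), 0, g, 0.7)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(0.7)

    def test_isolated_node_errors(self):
        g = AdjacencyGraph(3, [[1], [0], []])
        with pytest.raises(ValueError, match="no neighbors"):
            icar_full_conditional(np.zeros(3), 2, g, 1.0)

    def test_matches_brute_force_conditional_on_path4(self):
        """The ICAR conditional (neighbor mean, sigma^2/n_i) agrees with
        conditioning the joint improper density by completing the square
        of v_i in v' Q v."""
        g = AdjacencyGraph(4, [[1], [0, 2], [1, 3], [2]])
        Q = icar_precision(g).toarray()
        v = np.array([0.3, -1.2, 0.8, 2.0])
        sigma = 0.6
        for i in range(4):
            mean, sd = icar_full_conditional(v, i, g, sigma)
            # exp(-(v'Qv)/(2s^2)) in v_i: precision Q_ii/s^2,
            # mean -sum_{j!=i} Q_ij v_j / Q_ii
            others = [j for j in range(4) if j != i]
            brute_mean = -Q[i, others] @ v[others] / Q[i, i]
            brute_sd = sigma / np.sqrt(Q[i, i])
            assert mean == pytest.approx(brute_mean, abs=1e-12)
            assert sd == pytest.approx(brute_sd, abs=1e-12)


class TestAR1Density:
    def test_rho_zero_reduces_to_iid(self):
        l = np.array([0.5, -1.0, 0.2])
        got = ar1_log_density(l, 0.0, 0.8)
        want = stats.norm.logpdf(l, scale=0.8).sum()
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_dense_mvn_oracle(self):
        l = np.array([0.1, -0.2, 0.3])
        rho, sigma = 0.5, 1.0
        # stationary AR(1) covariance: sigma^2/(1-rho^2) * rho^|i-j|
        idx = np.arange(3)
        cov = sigma**2 / (1 - rho**2) * rho ** np.abs(idx[:, None] - idx[None, :])
        want = stats.multivariate_normal.logpdf(l, mean=np.zeros(3), cov=cov)
        assert ar1_log_density(l, rho, sigma) == pytest.approx(want, abs=1e-10)

    def test_scaling_change_of_variables(self):
        rng = np.random.default_rng(0)
        l = rng.normal(size=12)
        c = 2.5
        base = ar1_log_density(l, 0.6, 0.9)
        scaled = ar1_log_density(c * l, 0.6, c * 0.9)
        assert scaled - base == pytest.approx(-12 * np.log(c), abs=1e-10)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ar1_log_density(np.zeros(3), 1.0, 1.0)

    def test_precision_matches_density(self):
        """The tridiagonal precision reproduces the density quadratic form."""
        rng = np.random.default_rng(1)
        l = rng.normal(size=6)
        rho, sigma = 0.4, 0.7
        Q = ar1_precision(6, rho, sigma)
        quad = -0.5 * l @ Q @ l
        sign, logdet = np.linalg.slogdet(Q)
        const = 0.5 * logdet - 3 * np.log(2 * np.pi)
        assert ar1_log_density(l, rho, sigma) == pytest.approx(quad + const,
                                                               abs=1e-9)


class TestInteractionPrecision:
    @pytest.fixture()
    def grid22(self):
        return lattice_graph(2, 2)

    @pytest.mark.parametrize("itype,rank_fn", [
        ("I", lambda I, T: I * T),
        ("II", lambda I, T: I * (T - 1)),
        ("III", lambda I, T: T * (I - 1)),
        ("IV", lambda I, T: (I - 1) * (T - 1)),
    ])
    def test_ranks_match_numeric_rank(self, grid22, itype, rank_fn):
        T = 3
        Q, rank = interaction_precision(itype, grid22, T)
        assert rank == rank_fn(4, T)
        numeric = np.linalg.matrix_rank(Q.toarray(), tol=1e-9)
        assert numeric == rank

    def test_type_one_diagonal(self, grid22):
        Q, rank = interaction_precision("I", grid22, 3, sigma_phi=2.0)
        np.testing.assert_allclose(Q.toarray(), np.eye(12) / 4.0)
        assert rank == 12

    def test_type_three_rows_sum_to_zero(self, grid22):
        Q, _ = interaction_precision("III", grid22, 3)
        np.testing.assert_allclose(np.asarray(Q.sum(axis=1)).ravel(), 0,
                                   atol=1e-12)

    def test_disconnected_graph_rejected_for_structured_types(self):
        g = AdjacencyGraph(4, [[1], [0], [3], [2]])
        with pytest.raises(ValueError, match="connected"):
            interaction_precision("III", g, 3)

    def test_icar_rw1_structure_rows(self):
        np.testing.assert_allclose(
            np.asarray(rw1_precision(5).sum(axis=1)).ravel(), 0, atol=1e-12)
        g = lattice_graph(3, 3)
        np.testing.assert_allclose(
            np.asarray(icar_precision(g).sum(axis=1)).ravel(), 0, atol=1e-12)


class TestSamplers:
    @pytest.mark.parametrize("itype", ["I", "II", "III", "IV"])
    def test_prior_quadratic_form_consistency(self, itype):
        """phi' Q phi / rank ~ sigma^2 scale check: samples from each
        constrained interaction prior have unit normalized quadratic
        form under the matching precision (within 10% over 1000 draws)."""
        g = lattice_graph(3, 3)
        T = 6
        sigma = 0.7
        rng = np.random.default_rng(7)
        Q, rank = interaction_precision(itype, g, T, sigma_phi=sigma)
        Qd = Q.toarray()
        total = 0.0
        n_draws = 1000
        for _ in range(n_draws):
            phi = sample_interaction(itype, g, T, sigma, rng).ravel()
            total += phi @ Qd @ phi
        assert total / (n_draws * rank) == pytest.approx(1.0, rel=0.1)

    def test_constrained_icar_determinism(self):
        g = lattice_graph(3, 3)
        a = sample_constrained_icar(g, 0.5, np.random.default_rng(3))
        b = sample_constrained_icar(g, 0.5, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_type_iii_month_fields_sum_to_zero(self):
        g = lattice_graph(3, 3)
        phi = sample_interaction("III", g, 5, 1.0, np.random.default_rng(4))
        np.testing.assert_allclose(phi.sum(axis=0), 0, atol=1e-10)

    def test_ar1_invalid_rho(self):
        with pytest.raises(ValueError):
            sample_ar1(10, 1.2, 1.0, np.random.default_rng(0))
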