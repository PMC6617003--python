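import numpy as np
import pytest

from stmort import (AdjacencyGraph, SpaceTimePanel, lattice_graph,
                    read_adjacency, read_panel, weight_matrix,
                    write_adjacency, write_panel)
from stmort.core_data import (AdjacencyError, ModelConfig,
                              PanelValidationError, SchemaError)


def make_panel(I=4, T=3, seed=0):
    rng = np.random.default_rng(seed)
    return SpaceTimePanel(
        area_ids=[f"A{i}" for i in range(I)],
        month_index=[f"2012-{t + 1:02d}" for t in range(T)],
        deaths=rng.poisson(20, (I, T)),
        offset_pop=rng.integers(1000, 5000, (I, T)),
        pollutant=rng.normal(30, 10, (I, T)),
        temperature=rng.normal(12, 9, (I, T)),
        humidity=rng.uniform(40, 95, (I, T)),
        wind=rng.uniform(1, 6, (I, T)),
        deprivation=rng.normal(0, 8, I),
    )


class TestPanelIO:
    def test_round_trip_identity(self, tmp_path):
        panel = make_panel()
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        back = read_panel(path)
        assert back.area_ids == panel.area_ids
        assert back.month_index == panel.month_index
        np.testing.assert_array_equal(back.deaths, panel.deaths)
        np.testing.assert_allclose(back.pollutant, panel.pollutant)
        np.testing.assert_allclose(back.deprivation, panel.deprivation)

    def test_negative_death_names_cell(self, tmp_path):
        panel = make_panel()
        df = panel.to_long()
        df.loc[1, "deaths"] = -1
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="A0"):
            read_panel(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        df = make_panel().to_long().drop(columns=["wind"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="wind"):
            read_panel(path)

    def test_ragged_panel_rejected(self, tmp_path):
        df = make_panel().to_long().iloc[:-1]
        path = tmp_path / "ragged.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="ragged"):
            read_panel(path)

    def test_generator_dimension_contract(self, tmp_path):
        from stmort import TrueParams, simulate_covariates, simulate_panel
        graph = lattice_graph(5, 5)
        cov = simulate_covariates(25, 6, seed=0)
        sim = simulate_panel(TrueParams(), graph, cov, seed=1)
        path = tmp_path / "sim.csv"
        write_panel(sim.panel, path)
        panel = read_panel(path)
        assert panel.shape == (25, 6)

    def test_humidity_bounds_enforced(self):
        panel = make_panel()
        with pytest.raises(PanelValidationError, match="humidity"):
            SpaceTimePanel(**{**panel.__dict__, "humidity": panel.humidity + 200})


class TestAdjacencyIO:
    def test_lattice_round_trip(self, tmp_path):
        g = lattice_graph(2, 2)
        path = tmp_path / "adj.gal"
        write_adjacency(g, path)
        back, warnings = read_adjacency(path)
        assert back.neighbor_lists == g.neighbor_lists
        assert warnings == []
        assert all(len(n) == 2 for n in back.neighbor_lists)

    def test_asymmetry_error_names_areas(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("2\nA 1\nB\nB 0\n")
        with pytest.raises(AdjacencyError, match="asymmetric"):
            read_adjacency(path)

    def test_self_loop_error(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("1\nA 1\nA\n")
        with pytest.raises(AdjacencyError, match="self-loop"):
            read_adjacency(path)

    def test_isolated_area_warned(self, tmp_path):
        path = tmp_path / "iso.gal"
        path.write_text("3\nA 1\nB\nB 1\nA\nC 0\n")
        graph, warnings = read_adjacency(path)
        assert graph.isolated_areas() == [2]
        assert any("C" in w for w in warnings)

    def test_symmetry_invariant_of_construction(self):
        with pytest.raises(AdjacencyError):
            AdjacencyGraph(n_areas=2, neighbor_lists=[[1], []])


@pytest.fixture()
def path3():
    return AdjacencyGraph(n_areas=3, neighbor_lists=[[1], [0, 2], [1]])


class TestWeightMatrix:
    def test_binary(self, path3):
        W = weight_matrix(path3, "binary")
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(W, expected)

    def test_row_standardized(self, path3):
        W = weight_matrix(path3, "row_standardized")
        np.testing.assert_allclose(W[1], [0.5, 0, 0.5])
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_globally_standardized(self, path3):
        # mean row sum of the path graph is (1+2+1)/3 = 4/3
        W = weight_matrix(path3, "globally_standardized")
        nz = W[W > 0]
        np.testing.assert_allclose(nz, 0.75)

    def test_global_total_equals_edges_over_mean_rowsum(self):
        g = lattice_graph(3, 4)
        W = weight_matrix(g, "globally_standardized")
        n_directed = sum(len(n) for n in g.neighbor_lists)
        mean_rowsum = n_directed / g.n_areas
        np.testing.assert_allclose(W.sum(), n_directed / mean_rowsum)

    def test_row_standardized_rejects_isolated(self):
        g = AdjacencyGraph(n_areas=2, neighbor_lists=[[], []])
        with pytest.raises(AdjacencyError):
            weight_matrix(g, "row_standardized")


class TestModelConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(spline_df=(4, 3, 2), interaction_type="II")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = ModelConfig.from_yaml(path)
        assert back.spline_df == (4, 3, 2)
        assert back.interaction_type == "II"
        assert back.mcmc.thin == cfg.mcmc.thin

    def test_invalid_interaction_type(self):
        with pytest.raises(ValueError, match="interaction_type"):
            ModelConfig(interaction_type="V")

    def test_defaults_match_protocol(self):
        cfg = ModelConfig()
        assert cfg.coef_prior_variance == 1_000_000
        assert cfg.hyper_sd_upper == 10
        assert cfg.spline_df == (3, 2, 3)
        assert cfg.mcmc.n_keep == 2500 and cfg.mcmc.thin == 50
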