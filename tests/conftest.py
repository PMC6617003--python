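import numpy as np
import pytest

from stmort import (MCMCSettings, ModelConfig, TrueParams, lattice_graph,
                    simulate_covariates, simulate_panel)


@pytest.fixture(scope="session")
def grid44():
    return lattice_graph(4, 4)


@pytest.fixture(scope="session")
def fast_settings():
    """Short chains for unit tests (the protocol defaults are far longer)."""
    return MCMCSettings(n_chains=2, burn_in=300, n_keep=150, thin=1)


@pytest.fixture(scope="session")
def config(fast_settings):
    return ModelConfig(mcmc=fast_settings)


@pytest.fixture(scope="session")
def small_sim(grid44):
    cov = simulate_covariates(16, 18, seed=11)
    return simulate_panel(TrueParams(), grid44, cov, seed=12)


def simulate_quick(graph, T, truth=None, seed=0):
    cov = simulate_covariates(graph.n_areas, T, seed=seed)
    return simulate_panel(truth or TrueParams(), graph, cov, seed=seed + 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
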