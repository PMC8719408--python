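import numpy as np
import pytest

from apomap import ChainConfig, run_chains
from apomap.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_panel():
    """4x4 lattice, 4 periods, 4 outcomes — desk-scale panel with truth."""
    cfg = GeneratorConfig(n_rows=4, n_cols=4, denom_range=(1000, 3000))
    return generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def fitted(small_panel):
    """One modest shared fit reused by diagnostics/reporting/validation tests."""
    data, graph, truth = small_panel
    cfg = ChainConfig(n_chains=2, n_iterations=6000, burn_in=1000, thin=5,
                      base_seed=5)
    samples = run_chains(data, graph, config=cfg)
    return data, graph, truth, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
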