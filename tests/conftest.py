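import numpy as np
import pytest

from knotminer import GeneratorConfig, load_superfamily_definitions, simulate_bundle


@pytest.fixture(scope="session")
def sf_defs():
    return load_superfamily_definitions()

@pytest.fixture(scope="session")
def sf_by_name(sf_defs):
    return {d.name: d for d in sf_defs}


@pytest.fixture(scope="session")
def small_bundle():
    """A seeded 16-gene synthetic dataset shared by integration tests."""
    return simulate_bundle(GeneratorConfig(n_toxin_genes=16, seed=101))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
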