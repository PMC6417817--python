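import numpy as np
import pytest

from kircall import AlleleLibrary, SimulationConfig, extract_unique_kmers


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_library() -> AlleleLibrary:
    """Two genes with distinct sequences plus allelic variation."""
    return AlleleLibrary(
        {
            "GENEA": [("001", "AAAACCCC"), ("002", "TAAAACCC")],
            "GENEB": [("001", "GGGGTTTT")],
        }
    )


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Small but fully featured simulated cohort configuration."""
    return SimulationConfig(seed=11, n_samples=120)


@pytest.fixture(scope="session")
def small_index(small_sim_config):
    from kircall import simulate_allele_library

    library = simulate_allele_library(small_sim_config)
    return library, extract_unique_kmers(library, 30)
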