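import numpy as np
import pytest

from chromoshift.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study: 2 x 2 Mb genome, 5 SSRs, 4 SNRs."""
    return SimulationConfig(n_chroms=2, chrom_length=2_000_000,
                            n_ssr=5, n_snr=4, seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_config):
    """(truth, tracks, fragments, counts) for the scaled-down study."""
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
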