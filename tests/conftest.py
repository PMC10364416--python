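import warnings

import pytest

from epilink.synth import SynthConfig, simulate_dataset
from epilink.reconstruct import reconstruct_all


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulated world, shared across tests (seed 42)."""
    return simulate_dataset(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    """Reconstructed networks on the default world."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_all(default_dataset, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, small world for unit-level pipeline tests."""
    cfg = SynthConfig(n_enh=200, n_prom=30, chrom_length=4_000_000, seed=7)
    return simulate_dataset(cfg)
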