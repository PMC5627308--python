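import numpy as np
import pytest

from trcensus import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def seed_panel():
    """Default seed panel used by census-level tests."""
    return sd.make_seed_set()


@pytest.fixture(scope="session")
def small_dataset():
    """Zero-noise dataset with every family planted (6 genomes)."""
    return sd.make_dataset(
        6, {"TR1": 1, "TRi": 1, "TR3": 1, "FdR": 1, "dcTR1": 1},
        frac_trx3=1.0, n_background=3, mutation_rate=0.0, seed=5)
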