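import numpy as np
import pytest

from c4recruit.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced benchmark for structural (non-recovery) tests."""
    cfg = SynthConfig(seed=11, n_genes_per_species=120, n_clusters=4,
                      regulon_size=8, n_c4_genes=2)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark at its default study conditions."""
    return generate_dataset(SynthConfig(seed=0))
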