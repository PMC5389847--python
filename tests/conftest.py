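import numpy as np
import pytest

from gcorf.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced synthetic dataset reused by read-only tests."""
    config = SyntheticConfig(
        n_species=8,
        n_proteins_per_species=40,
        seed=42,
        mixture={
            "orphan": 0.25,
            "genus_orphan": 0.25,
            "intermediate": 0.25,
            "ancient": 0.25,
        },
    )
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
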