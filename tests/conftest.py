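import numpy as np
import pytest

from gibra import SyntheticConfig, simulate
from gibra.diversity import rarefy


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study (38 samples, 87 features)."""
    return simulate(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def rarefied(dataset):
    return rarefy(dataset.genus_counts, 45_000, seed=12)


@pytest.fixture(scope="session")
def rel_table(rarefied):
    return rarefied.relative_abundance()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def null_config(**overrides) -> SyntheticConfig:
    """Study design with every planted effect switched off."""
    cfg = SyntheticConfig(planted_genus_effects={},
                          host_group_shifts={},
                          marble_features={}, openfield_features={},
                          **overrides)
    return cfg
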