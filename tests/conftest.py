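import pytest

from pssmpp.synthetic import FixtureConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-signal dataset for fast unit tests (~500 residues)."""
    return generate_dataset(
        FixtureConfig(n_chains=12, chain_length=(30, 60), n_scales=8,
                      n_informative=2, seed=7)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Dataset at the default study conditions (60 chains, 20 scales)."""
    return generate_dataset(FixtureConfig(seed=1))


@pytest.fixture
def four_scales(tiny_dataset):
    return tiny_dataset.scales[:4]
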