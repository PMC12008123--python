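import pytest

from supenh.synthetic import SyntheticConfig, default_embedding_fixtures, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal dataset: AAA/GGG enriched in midstream of positives."""
    return generate_dataset(
        SyntheticConfig(n_pos=200, n_neg=200, length_range=(150, 900), seed=11)
    )


@pytest.fixture(scope="session")
def embedding_fixtures():
    """Default three 64-d Gaussian embedding matrices for k = 4, 5, 6."""
    return default_embedding_fixtures(seed=5)
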