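import numpy as np
import pytest

from endocorr import (
    MixtureConfig,
    enrichment_screen,
    generate_dataset,
    marker_correlation_profile,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic cohort (128 samples, 2000 genes, seed 42)."""
    return generate_dataset(MixtureConfig(seed=42))


@pytest.fixture(scope="session")
def default_profile(default_dataset):
    return marker_correlation_profile(default_dataset.expression)


@pytest.fixture(scope="session")
def default_screen(default_profile):
    return enrichment_screen(default_profile, threshold=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
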