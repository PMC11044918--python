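import numpy as np
import pytest

from survaug.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete paired dataset shared by fast tests."""
    return generate(SyntheticConfig(n_samples=200, d_A=24, d_B=12, k_latent=2,
                                    seed=11), test_frac=0.15, val_frac=0.15)


@pytest.fixture(scope="session")
def tiny_missing_dataset():
    """Small dataset with 80% of train+val modality-B rows removed."""
    return generate(SyntheticConfig(n_samples=300, d_A=24, d_B=12, k_latent=2,
                                    missing_fraction=0.8, seed=13),
                    test_frac=0.15, val_frac=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
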