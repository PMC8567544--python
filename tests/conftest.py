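import numpy as np
import pytest

from lmfda import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic bundle for fast pipeline tests."""
    cfg = SynthConfig(
        n_diseases=30,
        n_drugs=40,
        latent_dim=4,
        target_density=0.1,
        fingerprint_bits=64,
        semantic_noise=0.02,
        flip_noise=0.0,
        seed=11,
    )
    bundle, truth = generate_bundle(cfg)
    return bundle, truth


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's default world (120 diseases x 150 drugs, seed 7)."""
    bundle, truth = generate_bundle(SynthConfig())
    return bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
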