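import numpy as np
import pytest

from aeslice.phantom import (PhantomSpec, make_gradient_scheme, make_phantom,
                             simulate_dwi)


@pytest.fixture(scope="session")
def phantom_field():
    """Default 64x64x17 phantom (seeded)."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def phantom_dwi(phantom_field):
    """Noiseless DWI simulation of the default phantom (3 b0 + 15 dirs)."""
    grads = make_gradient_scheme(15, 700.0, n_b0=3, seed=42)
    return simulate_dwi(phantom_field, grads)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained autoencoder for contract (shape/range) tests."""
    from aeslice.autoencoder import AEConfig, ConvAutoencoder

    cfg = AEConfig(input_size=(32, 32), block_channels=(4, 8, 8, 16),
                   tail_channels=(16, 16), latent_channels=8, seed=0)
    return ConvAutoencoder(cfg)
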