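import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240524)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """5 grades x 6 phantoms at 64 px, shared across tests that only read them."""
    from retwave import synthetic

    cfg = synthetic.PhantomConfig(image_side=64, seed=7)
    manifest, images = synthetic.generate_dataset(6, cfg)
    return cfg, manifest, images
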