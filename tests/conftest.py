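import numpy as np
import pytest

from rmtfnet import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_batch():
    """Eight 64x64 phantoms with lesions, the CPU-scale training set."""
    imgs, msks = [], []
    for i in range(8):
        im, mk = generate_phantom(
            PhantomConfig(size=64, seed=100 + i, lesion_probability=1.0))
        imgs.append(im)
        msks.append(mk)
    return np.stack(imgs), np.stack(msks)
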