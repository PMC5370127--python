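import numpy as np
import pytest

from shadowcyte.synthetic import SynthParams, generate_smear


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_smear():
    """One 60-cell smear under default conditions, shared across tests."""
    params = SynthParams(seed=0)
    img, truth = generate_smear(params)
    return params, img, truth


@pytest.fixture(scope="session")
def random_patches():
    """Twenty seeded random uint8 64x64 patches."""
    gen = np.random.default_rng(7)
    return [gen.integers(0, 256, size=(64, 64)).astype(np.uint8) for _ in range(20)]
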