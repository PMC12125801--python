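import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask_pairs(rng):
    """200 random 32x32 binary mask pairs with varied density, none empty."""
    pairs = []
    while len(pairs) < 200:
        density = rng.uniform(0.05, 0.6)
        gt = (rng.random((32, 32)) < density).astype(np.uint8)
        pred = (rng.random((32, 32)) < density).astype(np.uint8)
        if gt.any() and pred.any():
            pairs.append((gt, pred))
    return pairs


@pytest.fixture(scope="session")
def small_phantom():
    from msaunet.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(seed=42))
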