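import numpy as np
import pytest

from tpunet.arch import ArchConfig, TPUNet
from tpunet.phantoms import PhantomParams, generate_phantom, worst_case_fixtures


@pytest.fixture(scope="session")
def tiny_arch() -> ArchConfig:
    return ArchConfig(base_channels=8)


@pytest.fixture(scope="session")
def tiny_net(tiny_arch) -> TPUNet:
    """One shared small network for shape/range/gradient checks."""
    return TPUNet(tiny_arch, seed=0)


@pytest.fixture(scope="session")
def phantom_batch():
    """Eight deterministic 64x64 phantoms as (images, masks) float batches."""
    params = PhantomParams(image_size=64, seed=0)
    images, masks = [], []
    for k in range(1, 9):
        img, mask = generate_phantom(params, k)
        images.append((img - 0.5) / 0.5)
        masks.append(mask)
    return (
        np.stack(images)[:, None].astype(np.float32),
        np.stack(masks)[:, None].astype(np.float32),
    )


@pytest.fixture(scope="session")
def edge_fixtures():
    return worst_case_fixtures(image_size=64)


def random_prob_mask(rng, shape=(2, 1, 8, 8)):
    """A random (probability map, binary mask) pair in float64."""
    p = rng.uniform(0.02, 0.98, size=shape)
    g = (rng.uniform(size=shape) > 0.6).astype(np.float64)
    return p, g
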