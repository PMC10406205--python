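import numpy as np
import pytest

from longlesion.io_volumes import LesionMask, Volume
from longlesion.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 48-voxel phantom with 3 lesions, shared across tests."""
    cfg = PhantomConfig(shape=(48, 48, 48), n_lesions=3,
                        lesion_radius_range=(2.0, 3.5), seed=42)
    vol, mask, tissue, atlas = make_phantom(cfg)
    return {"cfg": cfg, "vol": vol, "mask": mask, "tissue": tissue, "atlas": atlas}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask_pair(rng, shape=(16, 16, 16), p=0.1):
    """A random (pred, gt) mask pair for oracle comparisons."""
    pred = LesionMask((rng.random(shape) < p).astype(np.uint8))
    gt = LesionMask((rng.random(shape) < p).astype(np.uint8))
    return pred, gt


@pytest.fixture()
def flat_volume():
    return Volume(np.full((24, 24, 24), 0.5, dtype=np.float32))
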