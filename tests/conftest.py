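import numpy as np
import pytest

from niddl import synth
from niddl.models import ArchitectureSpec, build_model

TINY_SPEC = dict(levels=2, base_channels=4, blocks_per_level=1,
                 bottleneck_blocks=1)


@pytest.fixture(scope="session")
def tiny_unet():
    """A small fixed-channel U-Net for fast functional tests."""
    return build_model(ArchitectureSpec(family="unet_fixed", **TINY_SPEC),
                       seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A 20-cell synthetic scene pair at photon level 200."""
    clean, nuclei = synth.make_nuclei_scene((12, 48, 48), 20, 200.0, seed=7)
    noisy = synth.corrupt(clean, synth.NoiseSpec(photon_level=200.0), seed=8)
    return clean, noisy, nuclei


def scene_pairs(n, shape=(12, 48, 48), n_cells=12, photon=200.0, seed0=0):
    pairs = []
    for i in range(n):
        clean, _ = synth.make_nuclei_scene(shape, n_cells, photon,
                                           seed=seed0 + i)
        noisy = synth.corrupt(clean, synth.NoiseSpec(photon_level=photon),
                              seed=seed0 + 50000 + i)
        pairs.append((noisy.data, clean.data))
    return pairs
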