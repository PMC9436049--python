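import numpy as np
import pytest

from concord import MaskGrid, ObserverSet, assemble_observer_set


def mask_from_array(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return MaskGrid(np.asarray(arr, dtype=np.uint8), spacing, origin)


def random_panel(rng, shape=(8, 8, 8), n_obs=4, density=0.4, spacing=(1.0, 1.0, 1.0)):
    """Random iid panel used by oracle and property tests; guarantees a
    non-empty, non-full union so agreement statistics are well defined."""
    while True:
        masks = [
            mask_from_array(rng.random(shape) < density, spacing=spacing)
            for _ in range(n_obs)
        ]
        counts = sum(m.voxels.astype(int) for m in masks)
        if 0 < counts.max() and (counts == n_obs).sum() < counts.size:
            return assemble_observer_set(
                masks, [f"obs{i}" for i in range(n_obs)], "random-panel"
            )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel(rng) -> ObserverSet:
    return random_panel(rng)


@pytest.fixture
def identical_panel() -> ObserverSet:
    """Nine identical observers around a small ellipsoid-ish blob."""
    vox = np.zeros((12, 12, 12), dtype=np.uint8)
    vox[3:9, 4:8, 3:10] = 1
    vox[5:7, 2:10, 5:8] = 1
    m = mask_from_array(vox)
    return assemble_observer_set([m] * 9, [f"obs{i}" for i in range(9)], "identical")
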