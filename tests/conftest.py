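import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plnm_radiomics.imaging import DiscretizedVolume, ImageVolume, Mask


def random_discretized(rng, max_side=6, max_levels=8) -> DiscretizedVolume:
    """Random small discretized volume with a random (non-empty) mask."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    ng = int(rng.integers(1, max_levels + 1))
    lvl = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < rng.uniform(0.4, 1.0)
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    lvl = lvl * mask
    # n_levels = number of levels actually admissible (keep declared ng)
    return DiscretizedVolume(levels=lvl, n_levels=ng, bin_width=1.0, mask=mask)


def strip_volume(values, mask=None) -> tuple[ImageVolume, Mask]:
    """1D strip along x as a (n,1,1) volume."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    vol = ImageVolume(arr)
    m = Mask(np.ones_like(arr, dtype=bool) if mask is None else np.asarray(mask).reshape(arr.shape))
    return vol, m


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
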