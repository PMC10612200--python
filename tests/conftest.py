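import numpy as np
import pytest

from mrfusion.io_formats import AnnotatedSlice
from mrfusion.radiomics import DiscretizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, size=8, ng=5, mask_density=0.8):
    """Random discretized ROI on a size x size grid with a random mask."""
    mask = rng.random((size, size)) < mask_density
    if not mask.any():
        mask[size // 2, size // 2] = True
    levels = np.zeros((size, size), dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    present = np.unique(levels[mask])
    ng_eff = int(present.max())
    return DiscretizedROI(levels, ng_eff, mask)


@pytest.fixture
def roi_factory(rng):
    return lambda **kw: random_roi(rng, **kw)


@pytest.fixture
def phantom_slice(rng):
    """An 80 x 80 noisy slice with an off-center elliptical ROI."""
    img = rng.normal(100.0, 2.0, (80, 80))
    rr, cc = np.mgrid[0:80, 0:80]
    mask = ((rr - 42) / 14.0) ** 2 + ((cc - 38) / 10.0) ** 2 <= 1.0
    img[mask] += 3.0
    return AnnotatedSlice(img, mask, (1.0, 1.0), "T2w")
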