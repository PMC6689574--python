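import numpy as np
import pytest

from chromashift.colour_core import RegionMask, srgb_to_xyz, xyz_to_lab


def region_mean_oracle(pixels: np.ndarray, include: np.ndarray) -> tuple[float, float, float]:
    """Naive per-pixel loop oracle for the region-mean Lab.

    Iterates included pixels one by one through the scalar conversion
    operations and accumulates a plain arithmetic mean; deliberately shares
    no code with the vectorised masked-mean implementation it arbitrates.
    """
    total = np.zeros(3)
    n = 0
    h, w = include.shape
    for i in range(h):
        for j in range(w):
            if include[i, j]:
                lab = xyz_to_lab(srgb_to_xyz(pixels[i, j].astype(float)))
                total += np.asarray(lab)
                n += 1
    assert n > 0
    return tuple(total / n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image_and_mask(rng):
    """Factory for random small sRGB images with random non-empty masks."""

    def make(height=32, width=32):
        pixels = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
        include = rng.random((height, width)) < 0.5
        if not include.any():
            include[height // 2, width // 2] = True
        return pixels, RegionMask(include=include)

    return make
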