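"""Shared fixtures: hand-built cells and random-image factories."""

import numpy as np
import pytest

from nucloc import CellImage, NucleusMask


@pytest.fixture
def hand_cell():
    """The 10-pixel worked example: eight pixels at 2, two at 6.

    The nucleus is the two bright pixels, so the localization is
    6 / ((2*6 + 8*2) / 10) = 6 / 2.8 = 2.142857...
    """
    fluor = np.zeros((4, 4))
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0:3] = mask[1, 0:3] = mask[2, 0:3] = True
    mask[3, 0] = True
    vals = [2.0] * 8 + [6.0, 6.0]
    fluor[mask] = vals
    nuc = np.zeros((4, 4), dtype=bool)
    nuc[fluor == 6.0] = True
    img = CellImage(fluor=fluor, cell_mask=mask, cell_id="hand")
    return img, NucleusMask(nuc)


def random_cell(rng, shape=(12, 12), n_pixels=None, low=1.0, high=100.0):
    """A random CellImage with an irregular mask for oracle tests."""
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    if n_pixels is not None:
        flat = np.flatnonzero(mask.ravel())
        if flat.size > n_pixels:
            drop = rng.choice(flat, flat.size - n_pixels, replace=False)
            mask.ravel()[drop] = False
    fluor = np.where(mask, rng.uniform(low, high, shape), 0.0)
    return CellImage(fluor=fluor, cell_mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
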