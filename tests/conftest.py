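"""Shared fixtures: small synthetic lesions and digital solids."""

from __future__ import annotations

import numpy as np
import pytest

from lesionrad.types import DiscretizedLesion, LesionVolume


def make_discretized(levels: np.ndarray, ng: int, spacing: float = 1.0) -> DiscretizedLesion:
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedLesion(levels=levels, n_levels=ng, mask=levels > 0, spacing=spacing)


def digital_sphere(radius_vox: float, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> np.ndarray:
    """Boolean ball of the given radius (voxel units along the first axis)."""
    spacing = np.asarray(spacing, dtype=float)
    r_mm = radius_vox * spacing[0]
    shape = (2 * np.ceil(r_mm / spacing) + 1 + 2 * margin).astype(int)
    grids = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= r_mm**2


def digital_ellipsoid(semi_mm, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    semi = np.asarray(semi_mm, dtype=float)
    shape = (2 * np.ceil(semi / spacing) + 1 + 2 * margin).astype(int)
    grids = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    return (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0


def random_small_lesion(rng: np.random.Generator, ng: int = 4, max_side: int = 12):
    """Random discretized blob in a <= max_side^3 box, >= 2 voxels."""
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < rng.uniform(0.4, 0.95)
    while mask.sum() < 2:
        mask = rng.random(shape) < 0.7
    levels[~mask] = 0
    return make_discretized(levels, ng)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def textured_volume(rng):
    """A moderately sized continuous-intensity lesion for preprocessing tests."""
    from scipy import ndimage

    shape = (24, 24, 10)
    img = ndimage.gaussian_filter(rng.normal(100, 30, shape), 1.0)
    mask = np.zeros(shape, bool)
    x, y, z = np.indices(shape)
    mask[((x - 12) ** 2 / 81 + (y - 12) ** 2 / 81 + (z - 5) ** 2 / 12.25) <= 1] = True
    return LesionVolume(img, mask, (1.0, 1.0, 3.0))
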