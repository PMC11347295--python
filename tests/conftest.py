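"""Shared fixtures: tiny programmatic scenes used across the test suite."""

import numpy as np
import pytest

from sonopath.scene import DEFAULT_TISSUES, LabelGrid, LabelScene, TissueAcoustics


@pytest.fixture(scope="session")
def sphere_grid():
    """65^3 grid (0.5 mm voxels) with a 10 mm radius sphere at the origin.

    Odd size so one voxel centre sits exactly at the world origin.
    """
    n, sp = 65, 0.5
    ax = (np.arange(n) - n // 2) * sp
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    labels = ((xx**2 + yy**2 + zz**2) <= 10.0**2).astype(np.int16)
    origin = np.full(3, -(n // 2) * sp)
    return LabelGrid(labels, [sp] * 3, origin)


@pytest.fixture(scope="session")
def slab_scene():
    """Water over a soft-tissue half-space with a flat interface at z=40 mm."""
    water = DEFAULT_TISSUES["water"]
    soft = DEFAULT_TISSUES["soft_tissue"]
    labels = np.zeros((80, 10, 200), dtype=np.int16)
    labels[:, :, 80:] = 1
    return LabelScene.build(
        labels,
        [0.5, 0.5, 0.5],
        [-20 + 0.25, -2.5 + 0.25, 0.25],
        {0: water, 1: soft},
        ambient=water,
    )


@pytest.fixture(scope="session")
def two_layer_scene():
    """Water | tissue slab (z in [30, 60] mm) | water: two flat interfaces."""
    water = DEFAULT_TISSUES["water"]
    soft = DEFAULT_TISSUES["soft_tissue"]
    labels = np.zeros((60, 8, 180), dtype=np.int16)
    labels[:, :, 60:120] = 1
    return LabelScene.build(
        labels,
        [0.5, 0.5, 0.5],
        [-15 + 0.25, -2 + 0.25, 0.25],
        {0: water, 1: soft},
        ambient=water,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
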