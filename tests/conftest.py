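"""Shared fixtures: small random phantoms for oracle comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from kbdose import StructureMask, VoxelGrid, sphere_mask


def random_mask(rng: np.random.Generator, grid: VoxelGrid, n_spheres=(1, 3)) -> StructureMask:
    """Union of a few random spheres — a compact random blob."""
    extent = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    vox = np.zeros(grid.shape, dtype=bool)
    for _ in range(rng.integers(n_spheres[0], n_spheres[1] + 1)):
        center = rng.uniform(0.25, 0.75, 3) * extent
        radius = rng.uniform(0.12, 0.3) * extent.min()
        vox |= sphere_mask(grid, center, radius).voxels
    return StructureMask(grid, vox)


def random_structure_pair(seed: int, shape=(14, 14, 14), spacing=(2.0, 2.0, 2.0)):
    """A random (GTV, OAR_CRIT) pair on a small grid; GTV always non-empty,
    OAR occasionally empty (a valid clinical degenerate)."""
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(shape, spacing)
    gtv = random_mask(rng, grid)
    while gtv.is_empty:  # pragma: no cover - sphere radii make this rare
        gtv = random_mask(rng, grid)
    if rng.uniform() < 0.05:
        oar = StructureMask(grid, np.zeros(grid.shape, dtype=bool))
    else:
        oar = random_mask(rng, grid)
    return gtv, oar


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def unit_grid():
    """21^3 grid at 1 mm — fine enough for exact mm-scale checks."""
    return VoxelGrid((21, 21, 21), (1.0, 1.0, 1.0))
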