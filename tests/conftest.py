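"""Shared fixtures: small phantoms and smooth random velocity fields.

Everything is generated programmatically at collection time; grids are kept
small (16^3 for unit mechanics, 32^3 for end-to-end behaviour) so the whole
suite stays CPU-friendly.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from voxmotion.fields import Grid3, VelocityField
from voxmotion.phantom import AnatomyConfig, build_phantom, generate_trace


def smooth_velocity(grid: Grid3, seed: int, max_voxels: float = 3.0, sigma: float = 4.0) -> VelocityField:
    """Gaussian-smoothed random velocity field with bounded voxel magnitude."""
    rng = np.random.default_rng(seed)
    comps = np.stack([gaussian_filter(rng.standard_normal(grid.shape), sigma) for _ in range(3)])
    spacing = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    comps_vox = comps / np.abs(comps).max()
    return VelocityField(grid, comps_vox * max_voxels * spacing)


@pytest.fixture(scope="session")
def grid24() -> Grid3:
    return Grid3((24, 24, 24), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def phantom16():
    """Tiny phantom for fast dataset/training mechanics tests."""
    grid = Grid3((16, 16, 16), (6.0, 6.0, 6.0))
    trace = generate_trace(60.0, amplitude_mm=10.0, amplitude_jitter=0.05, period_jitter=0.05, seed=21)
    return build_phantom(AnatomyConfig(grid=grid), trace)


@pytest.fixture(scope="session")
def phantom32():
    """Desk-scale phantom matching the end-to-end study conditions."""
    grid = Grid3((32, 32, 32), (3.0, 3.0, 3.0))
    trace = generate_trace(60.0, amplitude_mm=10.0, amplitude_jitter=0.05, period_jitter=0.05, seed=11)
    return build_phantom(AnatomyConfig(grid=grid), trace)
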