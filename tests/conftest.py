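"""Shared geometry builders and phantom fixtures."""

import numpy as np
import pytest

from hepatoseg.shape import ClosedSurface


def grid_mm(n, spacing=1.0):
    """Voxel-center coordinate grids for an n^3 volume."""
    ax = (np.arange(n) + 0.5) * spacing
    return np.meshgrid(ax, ax, ax, indexing="ij")


def sphere_surface(n=44, center=22.0, radius=16.0, spacing=1.0):
    x, y, z = grid_mm(n, spacing)
    occ = (x - center) ** 2 + (y - center) ** 2 + (z - center) ** 2 <= radius**2
    return ClosedSurface(occ, (spacing,) * 3)


def slab_surface(n=40, zmax=20):
    """Box whose top face (z = zmax mm) is flat and far from other faces."""
    occ = np.zeros((n, n, n), bool)
    occ[2:n - 2, 2:n - 2, 2:zmax] = True
    return ClosedSurface(occ)


@pytest.fixture(scope="session")
def noiseless_phantom():
    from hepatoseg import default_phantom
    return default_phantom(seed=7, grid_shape=(64, 64, 64), n_lesions=1)


@pytest.fixture(scope="session")
def training_phantom():
    from hepatoseg import default_phantom
    return default_phantom(seed=0, grid_shape=(64, 64, 64), n_lesions=1)
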