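import math

import numpy as np
import pytest

from scandose.decay_data import (
    EmissionLine,
    RadiationClass,
    RadionuclideDecayData,
    load_bundled_decay_table,
)
from scandose.phantom_transport import Region, VoxelPhantom


@pytest.fixture(scope="session")
def decay_table():
    return load_bundled_decay_table()


@pytest.fixture(scope="session")
def nuclides(decay_table):
    return {n.name: n for n in decay_table}


@pytest.fixture(scope="session")
def toy_phantom():
    """Two box organs inside a water body; 8 mm voxels."""
    grid = np.zeros((24, 20, 20), np.int32)
    grid[2:22, 2:18, 2:18] = 3
    grid[4:9, 5:15, 5:15] = 1
    grid[14:19, 5:15, 5:15] = 2
    regions = {
        1: Region(1, "A", "water", 1.05),
        2: Region(2, "B", "water", 1.02),
        3: Region(3, "remainder", "water", 1.0),
    }
    return VoxelPhantom(grid, (8.0, 8.0, 8.0), regions, tag="toy")


@pytest.fixture(scope="session")
def sphere_phantom():
    """Homogeneous water sphere with a central one-voxel source region.

    Returns (phantom, effective radius in mm of the voxelised sphere).
    """
    radius_mm, voxel_mm = 60.0, 4.0
    n = int(2 * radius_mm / voxel_mm) + 4
    grid = np.zeros((n, n, n), np.int32)
    c = (np.arange(n) + 0.5) * voxel_mm - n * voxel_mm / 2
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    inside = x**2 + y**2 + z**2 <= radius_mm**2
    grid[inside] = 1
    ci = n // 2
    grid[ci, ci, ci] = 2
    regions = {
        1: Region(1, "sphere", "water", 1.0),
        2: Region(2, "core", "water", 1.0),
    }
    phantom = VoxelPhantom(grid, (voxel_mm,) * 3, regions, tag="sphere")
    r_eff = (3 * int(inside.sum()) * voxel_mm**3 / (4 * math.pi)) ** (1 / 3)
    return phantom, r_eff


@pytest.fixture(scope="session")
def mono_gamma():
    """Single-line 300 keV gamma pseudo-nuclide."""
    return RadionuclideDecayData(
        "mono-gamma", 1.0, (EmissionLine(RadiationClass.GAMMA, 1.0, 0.3),)
    )


@pytest.fixture(scope="session")
def toy_nuclide():
    """Mixed photon + beta pseudo-nuclide for dose-chain tests."""
    return RadionuclideDecayData(
        "toy",
        5.0,
        (
            EmissionLine(RadiationClass.GAMMA, 0.5, 0.4),
            EmissionLine(RadiationClass.BETA_MINUS, 1.0, 0.15),
        ),
    )
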