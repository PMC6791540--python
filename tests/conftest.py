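import numpy as np
import pytest

from tumourmeter import Lattice, SimulationParams
from tumourmeter.ca import POP_A


@pytest.fixture
def small_params() -> SimulationParams:
    """Desk-scale parameters for fast unit tests (not the package defaults)."""
    return SimulationParams(dims=(48, 48, 30), total_days=20, treatment_start=10,
                            lam_len=5, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_cuboid(nx: int, ny: int, nz: int, pad: int = 3, voxel_edge: float = 1.0) -> Lattice:
    """Axis-aligned solid cuboid of POP_A cells sitting on the base plane."""
    state = np.zeros((nx + 2 * pad, ny + 2 * pad, nz + pad), dtype=np.uint8)
    state[pad : pad + nx, pad : pad + ny, 0:nz] = POP_A
    return Lattice(state, voxel_edge)


def make_hemisphere(radius: int, voxel_edge: float = 1.0) -> Lattice:
    """Voxelised hemisphere (z >= 0) of the given radius in voxels."""
    n = 2 * radius + 7
    state = np.zeros((n, n, radius + 4), dtype=np.uint8)
    c = n // 2
    x, y, z = np.indices(state.shape)
    state[(x - c) ** 2 + (y - c) ** 2 + z**2 <= radius**2] = POP_A
    return Lattice(state, voxel_edge)


def make_ball(radius: int, voxel_edge: float = 1.0) -> Lattice:
    """Voxelised full ball (for volume-counting oracles only)."""
    n = 2 * radius + 7
    state = np.zeros((n, n, n), dtype=np.uint8)
    c = n // 2
    x, y, z = np.indices(state.shape)
    state[(x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2] = POP_A
    return Lattice(state, voxel_edge)
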