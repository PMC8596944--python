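"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from fixflux.phantom import PhantomSpec, make_phantom
from fixflux.simulator import SimulationConfig, simulate_concentration
from fixflux.volumes import Mask, TensorVolume, VolumeGrid


@pytest.fixture(scope="session")
def phantom32():
    """32^3 anisotropic phantom shared by the simulator/regression suites."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32)))


@pytest.fixture(scope="session")
def outflux32(phantom32):
    """Default 48 h outflux concentration on the 32^3 phantom."""
    final, _ = simulate_concentration(
        phantom32.tensors, phantom32.tissue, SimulationConfig()
    )
    return final


@pytest.fixture()
def unit_grid():
    return VolumeGrid((8, 8, 8), (1.0, 1.0, 1.0))


def ball_mask(n: int, radius_vox: float, spacing=(1.0, 1.0, 1.0)) -> Mask:
    """Digital ball of the given voxel radius centred on an n^3 grid."""
    grid = VolumeGrid((n, n, n), spacing)
    c = np.arange(n) - (n - 1) / 2.0
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    return Mask(grid, np.sqrt(x**2 + y**2 + z**2) <= radius_vox)


def isotropic_tensors(mask: Mask, d: float) -> TensorVolume:
    comps = np.zeros((*mask.grid.shape, 6))
    for diag in (0, 3, 5):
        comps[..., diag] = np.where(mask.values, d, 0.0)
    return TensorVolume(mask.grid, comps)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
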