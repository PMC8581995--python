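import numpy as np
import pytest

from dippi.acquisition import Scheme
from dippi.physics import PhysicalConstants
from dippi.signal import FiberPopulation, MyelinPool, VoxelModel


@pytest.fixture(scope="session")
def consts7t():
    """7 T constants with the standard myelin susceptibility."""
    return PhysicalConstants(B0=7.0, chi_A_ppb=-100.0, chi_I_ppb=-100.0)


@pytest.fixture
def xy_crossing_voxel(consts7t):
    """Two fibers along x and y, half-myelinated axons with g = 0.7."""
    pool = MyelinPool(0.5, float(np.log(0.7)))
    pops = [
        FiberPopulation(np.array([1.0, 0.0, 0.0]), pool=pool),
        FiberPopulation(np.array([0.0, 1.0, 0.0]), pool=pool),
    ]
    return VoxelModel(pops, omega_bulk=None, phi_SE=None, eddy=None,
                      consts=consts7t)


@pytest.fixture
def single_tphase_scheme():
    return Scheme.dippi_shell(30, b=3.0, t_phases=(20.0,))
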