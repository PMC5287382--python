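import numpy as np
import pytest

from issmri import (
    AcquisitionParams,
    DiffusionClearanceModel,
    VoxelGrid,
    simulate_concentration_field,
)

SHAM = dict(D_star=2.770e-4, k_prime=0.648e-4)
ROTENONE = dict(D_star=5.828e-4, k_prime=0.333e-4)
MADOPAR = dict(D_star=3.645e-4, k_prime=0.500e-4)


@pytest.fixture(scope="session")
def grid64() -> VoxelGrid:
    return VoxelGrid.centered((64, 64, 64))


@pytest.fixture(scope="session")
def grid32() -> VoxelGrid:
    return VoxelGrid.centered((32, 32, 32))


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def sham_model() -> DiffusionClearanceModel:
    return DiffusionClearanceModel(**SHAM)


@pytest.fixture(scope="session")
def sham_conc(sham_model, grid32):
    """Noiseless sham concentration field at the acquisition schedule."""
    times_s = np.array(AcquisitionParams().time_points) * 3600.0
    return simulate_concentration_field(sham_model, grid32, times_s)
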