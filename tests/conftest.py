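import numpy as np
import pytest

from gbmsim.fields import GrowthParams, VoxelGrid


@pytest.fixture
def full_grid():
    """16^3 grid, 1 mm spacing, every voxel inside the mask."""
    return VoxelGrid(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0),
                     mask=np.ones((16, 16, 16), dtype=bool))


@pytest.fixture
def params():
    """Lesion-specific parameters estimated from the reference tumor."""
    return GrowthParams(rho=0.33, c_m=1e5, tau=0.85, eta=0.9, dt=1.0)
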