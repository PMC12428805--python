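import numpy as np
import pytest

from coronaflow.core import DisplacementField, EnFaceSlab
from coronaflow.synthetic import SLAB_STYLES, generate_slab_image


@pytest.fixture(scope="session")
def scp_img() -> EnFaceSlab:
    return generate_slab_image(SLAB_STYLES["SCP"], 304, seed=1)


@pytest.fixture(scope="session")
def dcp_img() -> EnFaceSlab:
    return generate_slab_image(SLAB_STYLES["DCP"], 304, seed=1)


@pytest.fixture(scope="session")
def cc_img() -> EnFaceSlab:
    return generate_slab_image(SLAB_STYLES["CC"], 304, seed=1)


@pytest.fixture(scope="session")
def small_dcp() -> EnFaceSlab:
    """Small textured fixture for fast flow tests."""
    return generate_slab_image(SLAB_STYLES["DCP"], 160, seed=3)


@pytest.fixture
def zero_field() -> DisplacementField:
    z = np.zeros((304, 304))
    return DisplacementField(z, z.copy())
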