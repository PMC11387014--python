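import numpy as np
import pytest

import mechanoscope as ms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small homogeneous phantom for fast unit tests."""
    return ms.PhantomSpec(
        grid_shape=(8, 8, 96),
        voxel_pitch_um=(2.0, 2.0, 2.0),
        sample_thickness_um=120.0,
        background_modulus_kpa=7.0,
        bulk_displacement_um=0.05,
        seed=7,
    )


@pytest.fixture
def geometry():
    return ms.AcquisitionGeometry(voxel_pitch_um=(2.0, 2.0, 2.0))
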