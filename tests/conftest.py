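import logging

import numpy as np
import pytest

from tuvi import AcquisitionParams, Bubble

logging.getLogger("tuvi").setLevel(logging.ERROR)


@pytest.fixture
def small_params():
    """A 32-channel acquisition, noise off, shallow record."""
    return AcquisitionParams(n_channels=32, noise_sigma=0.0, n_frames=1,
                             max_depth=45.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_bubble(x, z, amplitude=1.0):
    return Bubble(position=np.array([x, z], dtype=float), arc_coordinate=0.0,
                  segment_id=0, radial_offset=0.0, amplitude=amplitude)


@pytest.fixture
def point_bubble():
    return make_bubble(0.0, 30.0)
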