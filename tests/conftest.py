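import numpy as np
import pytest

from veinmap.synth import PhantomSpec
from veinmap.types import CameraIntrinsics


@pytest.fixture
def small_spec():
    """A reduced-size phantom for fast unit tests (geometry scaled ~1/3)."""
    return PhantomSpec(
        swir_shape=(160, 200),
        tof_shape=(48, 60),
        tof_intrinsics=CameraIntrinsics(
            fx=80.0, fy=80.0, cx=29.5, cy=23.5, k1=-0.2, k2=0.05
        ),
        vein_count=2,
        vein_width=5.0,
        vein_wiggle=10.0,
        pair_count=40,
        seed=11,
    )


@pytest.fixture
def plain_intrinsics():
    return CameraIntrinsics(fx=250.0, fy=250.0, cx=87.5, cy=71.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
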