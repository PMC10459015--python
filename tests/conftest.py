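import numpy as np
import pytest

from stemmap.direct_vo import make_frame
from stemmap.synthetic import StereoScene, default_intrinsics, render_stereo_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def K():
    return default_intrinsics()


@pytest.fixture(scope="session")
def scene():
    return StereoScene()


@pytest.fixture(scope="session")
def static_frame(K, scene):
    """A rendered reference frame with exact disparity (no motion)."""
    from stemmap.geometry import Twist6

    ref, _, disp = render_stereo_pair(scene, Twist6.zero(), K)
    return make_frame(ref, disp, K)
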