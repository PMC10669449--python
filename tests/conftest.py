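import numpy as np
import pytest

from dafdnet.network import NetworkConfig, build_dafdnet
from dafdnet.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest legal network: 32-px input, narrow stages, one Gabor scale."""
    return NetworkConfig(input_size=32, stage_channels=(4, 8, 16),
                         pf_channels=(4, 8, 16), gabor_scales=(1,))


@pytest.fixture(scope="session")
def tiny_net(tiny_cfg):
    return build_dafdnet(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(PhantomSpec(image_size=64, seed=7))
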