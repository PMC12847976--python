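import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import angioscreen as ag

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geo512() -> ag.ChipGeometry:
    return ag.ChipGeometry(shape=(512, 512), center=(256.0, 256.0), radius=150.0)


@pytest.fixture(scope="session")
def small_network(geo512):
    """One default-condition network with its clean rasterization."""
    net = ag.generate_network(ag.GrowthParams(), geo512, seed=3)
    image, labels = ag.rasterize(net, geo512)
    return net, image, labels


def make_bar_mask(shape=(700, 700), rows=(348, 353), cols=(300, 400), label=2):
    lab = np.zeros(shape, np.uint8)
    lab[rows[0] : rows[1], cols[0] : cols[1]] = label
    return ag.VesselMask(lab)
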