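import numpy as np
import pytest

from ewimap.geometry import ViewGeometry
from ewimap.phantom import build_mask, build_ring_mask
from ewimap.segments import VIEW_SEGMENTS, build_segment_model


@pytest.fixture(scope="session")
def model():
    return build_segment_model()


@pytest.fixture(scope="session")
def geom_4ch():
    return ViewGeometry(view_name="4ch", depth_max_mm=100.0)


@pytest.fixture(scope="session")
def sector_mask(geom_4ch, model):
    """Half-annulus 4-chamber wall, 1 mm grid, six segments along the arc."""
    return build_mask(geom_4ch, 25.0, 40.0, spacing_mm=1.0,
                      segments=VIEW_SEGMENTS["4ch"], model=model)


@pytest.fixture(scope="session")
def ring_mask(model):
    """Idealized full-ring biventricular annulus (all 24 segments)."""
    return build_ring_mask(model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
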