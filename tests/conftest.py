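import numpy as np
import pytest

from subtyperad.phantom import PhantomSpec, generate_case
from subtyperad.segmentation import ROIBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic class-B phantom case."""
    spec = PhantomSpec(n_cases=4, rng_seed=7)
    return generate_case(spec, "B", np.random.default_rng(7), case_id="fixture")


@pytest.fixture
def disk_image():
    """A 200-valued disk (radius 12) on a 10-valued background, with ROI."""
    rr, cc = np.mgrid[0:64, 0:64]
    mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2
    image = np.full((64, 64), 10.0)
    image[mask] = 200.0
    return image, mask, ROIBox(14, 14, 50, 50)
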