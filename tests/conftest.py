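import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from evradiomics.simulate import ImageSimSpec, simulate_volume


@pytest.fixture(scope="session")
def textured_volume():
    """A small synthetic volume with lesion + muscle VOIs, fixed seed."""
    spec = ImageSimSpec(grid_shape=(24, 24, 24), lesion_radius_mm=6.0,
                        lesion_center=(14.0, 14.0, 14.0), seed=7)
    return simulate_volume(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
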