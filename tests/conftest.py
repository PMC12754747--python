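import numpy as np
import pytest

import petalign as pa


@pytest.fixture(scope="session")
def small_scanner():
    """8 blocks x 2 rings toy scanner with coarse crystals."""
    bp = pa.make_cylindrical_blueprint(8, 2, 40.0, (24.0, 10.0, 24.0), ring_pitch=24.0)
    lut = pa.CrystalLUT.regular((24.0, 10.0, 24.0), (8, 2, 8))
    return bp, lut


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
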