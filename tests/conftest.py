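import numpy as np
import pytest

from auxforge import (BeamNetwork, PlanarDesign, gen_planar_auxetic,
                      gen_synthetic_organ)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def organ():
    return gen_synthetic_organ(seed=3)


@pytest.fixture(scope="session")
def reentrant_net():
    return gen_planar_auxetic(PlanarDesign(kind="reentrant", n1=6, n2=3,
                                           t=0.3))


@pytest.fixture()
def single_beam():
    return BeamNetwork([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], [[0, 1]], 0.8)
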