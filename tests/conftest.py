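import numpy as np
import pytest

from glymph.scheme import b1000_scheme
from glymph.synthetic import FiberSpec, make_phantom, uniform_phantom


@pytest.fixture(scope="session")
def scheme31():
    """b = 0 + 1000 s/mm2, 31 directions."""
    return b1000_scheme(31)


@pytest.fixture(scope="session")
def fiber_phantom():
    """32^3 structured phantom with a planted perivascular x elevation
    (ground-truth ALPS = 0.45/0.30 = 1.5)."""
    return make_phantom((32, 32, 32), FiberSpec(dxx=0.45e-3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def uniform16():
    return uniform_phantom((16, 16, 16), (0.3e-3, 0.3e-3, 1.4e-3), fw=0.0)
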