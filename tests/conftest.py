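import numpy as np
import pytest

from icdrecon import (
    FiniteDifferenceOperator,
    radial_mask,
    shepp_logan,
    true_cosupport,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160609)


@pytest.fixture(scope="session")
def phantom256():
    return shepp_logan(256)


@pytest.fixture(scope="session")
def fd_operator256():
    return FiniteDifferenceOperator((256, 256))


@pytest.fixture(scope="session")
def phantom_cosupport(phantom256, fd_operator256):
    return true_cosupport(phantom256, fd_operator256, tol=0.0)


@pytest.fixture(scope="session")
def radial12_mask256():
    return radial_mask((256, 256), 12)
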