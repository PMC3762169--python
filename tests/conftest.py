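import numpy as np
import pytest

from fiberodf import build_basis, hemisphere_grid, shell_scheme, subdivide_icosahedron


@pytest.fixture(scope="session")
def grid321():
    return hemisphere_grid(321)


@pytest.fixture(scope="session")
def grid81():
    return hemisphere_grid(81)


@pytest.fixture(scope="session")
def full642():
    return subdivide_icosahedron(3)


@pytest.fixture(scope="session")
def basis_b3000(grid321):
    return build_basis(shell_scheme(3000.0), grid321)


@pytest.fixture(scope="session")
def basis_b5000(grid321):
    return build_basis(shell_scheme(5000.0), grid321)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
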