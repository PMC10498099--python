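import numpy as np
import pytest

from ordose.phantoms import PhantomSpec, make_phantom
from ordose.quadrature import (
    build_energy_grid,
    build_fine_angular_quadrature,
    build_standard_angular_quadrature,
)


@pytest.fixture(scope="session")
def std_quad():
    return build_standard_angular_quadrature()


@pytest.fixture(scope="session")
def fine_quad():
    return build_fine_angular_quadrature()


@pytest.fixture(scope="session")
def photon_grid():
    return build_energy_grid("photon")


@pytest.fixture(scope="session")
def proton_grid():
    return build_energy_grid("proton")


@pytest.fixture(scope="session")
def compton_tables(std_quad, photon_grid):
    from ordose.xsections import build_compton_tables

    return build_compton_tables(std_quad, photon_grid)


@pytest.fixture(scope="session")
def electron_tables(std_quad, photon_grid):
    from ordose.xsections import build_electron_tables

    return build_electron_tables(photon_grid, std_quad)


@pytest.fixture(scope="session")
def proton_tables(std_quad, proton_grid):
    from ordose.xsections import build_proton_tables

    return build_proton_tables(proton_grid, std_quad)


@pytest.fixture
def water_cube():
    return make_phantom(PhantomSpec("water", size_mm=(80.0, 80.0, 80.0), voxel_mm=10.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20230913)
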