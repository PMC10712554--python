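import numpy as np
import pytest

from rotaxle import fixtures
from rotaxle.components import CrickParams, generate_crick_helix
from rotaxle.landscape import Landscape1D


#: straight alpha-helix (no supercoil), used across modules
STRAIGHT_HELIX = CrickParams(supercoil_radius_r0=0.0, supercoil_twist_w0=0.0,
                             minor_radius_r1=2.26, helix_twist_w1=100.0,
                             rise_per_res_d=1.51, n_res=10)


@pytest.fixture(scope="session")
def straight_chain():
    return generate_crick_helix(STRAIGHT_HELIX)


@pytest.fixture(scope="session")
def c5c3():
    return fixtures.c5c3_assembly()


@pytest.fixture(scope="session")
def c3c3():
    return fixtures.c3c3_assembly()


@pytest.fixture(scope="session")
def d8c4():
    return fixtures.d8c4_assembly()


@pytest.fixture(scope="session")
def d3c3():
    return fixtures.d3c3_assembly()


@pytest.fixture(scope="session")
def d3c5():
    return fixtures.d3c5_assembly()


@pytest.fixture(scope="session")
def flat_landscape():
    return Landscape1D("rot_z", np.arange(0.0, 360.0, 1.0), np.zeros(360))


@pytest.fixture(scope="session")
def two_well_landscape():
    """Symmetric degenerate double well: E = 0.3 cos(2 theta)."""
    return Landscape1D.from_function(
        lambda th: 0.3 * np.cos(2 * np.radians(th)), 1.0)
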