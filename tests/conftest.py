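import numpy as np
import pytest

from bifdesign.bifurcation import trace_diagram
from bifdesign.design import verification_grid
from bifdesign.fixtures import fig4_A3, fig5_A1, fig5_A1_isola, fig5_A1_open

#: ±10-fold band around the printed biosensor parameter values, used by the
#: recovery and determinism tests
PRINTED_VALUES = dict(
    p0=361.0, p1=30.0, p2=411.0, k=9.04e-2, R1=143.0, R2=300.0, dv=1.38, K1=10.0, K2=137.0
)


def tenfold_bounds(names):
    return tuple((PRINTED_VALUES[n] / 10, PRINTED_VALUES[n] * 10) for n in names)


@pytest.fixture(scope="session")
def s_grid():
    return verification_grid((0.1, 330.0))


@pytest.fixture(scope="session")
def mushroom_fixture():
    return fig5_A1()


@pytest.fixture(scope="session")
def mushroom_diagram(mushroom_fixture, s_grid):
    return trace_diagram(mushroom_fixture.model, s_grid)


@pytest.fixture(scope="session")
def isola_fixture():
    return fig5_A1_isola()


@pytest.fixture(scope="session")
def isola_diagram(isola_fixture, s_grid):
    return trace_diagram(isola_fixture.model, s_grid)


@pytest.fixture(scope="session")
def open_mushroom_diagram(s_grid):
    return trace_diagram(fig5_A1_open().model, s_grid)


@pytest.fixture(scope="session")
def phase_base_fixture():
    return fig4_A3()
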