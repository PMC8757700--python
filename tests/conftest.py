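import numpy as np
import pytest

from stentbench.material import CurveFamily, TangentLaw, UniaxialCurve
from stentbench.synthetic import make_curve_family, make_mini_stent


@pytest.fixture(scope="session")
def family() -> CurveFamily:
    """Default synthetic PLLA-like curve family on the full 3x3 grid."""
    return make_curve_family()


@pytest.fixture(scope="session")
def linear_family() -> CurveFamily:
    """Single linear (purely elastic) curve, slope 3000 MPa."""
    return CurveFamily(
        [UniaxialCurve([0.0, 0.5], [0.0, 1500.0], temperature=37.0, strain_rate=0.01)]
    )


@pytest.fixture(scope="session")
def law() -> TangentLaw:
    return TangentLaw(poisson_ratio=0.30)


@pytest.fixture(scope="session")
def mini_mesh():
    return make_mini_stent()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def single_hex_mesh():
    from stentbench.fem import HexMesh

    nodes = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    return HexMesh(nodes, np.arange(8)[None, :])
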