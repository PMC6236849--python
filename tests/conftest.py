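import numpy as np
import pytest

from cbctdose.grids import Geometry
from cbctdose.phantom import PhantomSpec, make_4dct
from cbctdose.grids import FOVRegion


@pytest.fixture(scope="session")
def spec32() -> PhantomSpec:
    """Coarse phantom (32^3 at 5 mm) used by most registration-free tests."""
    return PhantomSpec(size=(32, 32, 32), spacing_mm=(5.0, 5.0, 5.0), seed=11)


@pytest.fixture(scope="session")
def phantom32(spec32):
    return make_4dct(spec32)


@pytest.fixture(scope="session")
def phantom64():
    """Full-resolution phantom (64^3 at 2.5 mm), shared across heavy tests."""
    return make_4dct(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def fov120() -> FOVRegion:
    return FOVRegion("cylinder", (0.0, 0.0, 0.0), diameter=120.0, axis=2)


@pytest.fixture
def unit_geometry() -> Geometry:
    return Geometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), size=(8, 8, 8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
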