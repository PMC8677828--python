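import numpy as np
import pytest

from edgeup import GenerationConfig, PhantomSpec, build_library, rasterize_cube


@pytest.fixture(scope="session")
def axis_library():
    """Axis-aligned validation library (1-3 plane units)."""
    return build_library(GenerationConfig(angular_density=0))


@pytest.fixture(scope="session")
def small_library():
    """Axis-aligned 1+2-plane library (fast, no vertex units)."""
    return build_library(GenerationConfig(angular_density=0, max_planes=2))


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_volume(phantom_spec):
    return rasterize_cube(phantom_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
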