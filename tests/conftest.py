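import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmrikit.phantom import build_phantom, preset_spec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight-bundle phantom (40 mm along x, 2 mm voxels)."""
    return build_phantom(preset_spec("straight"))


@pytest.fixture(scope="session")
def arc_phantom():
    """Noiseless quarter-circle bundle phantom, radius 20 mm."""
    return build_phantom(preset_spec("arc"))


@pytest.fixture(scope="session")
def crossing_phantom():
    """Noiseless 90-degree crossing phantom, 16^3 grid."""
    return build_phantom(preset_spec("crossing"))


@pytest.fixture(scope="session")
def edema_phantom():
    """Noiseless straight bundle with a fw=0.6 collar."""
    return build_phantom(preset_spec("edema"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
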