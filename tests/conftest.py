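import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def template_model():
    from tifield.sphere import SphereModel

    return SphereModel()


@pytest.fixture(scope="session")
def coarse_grid(template_model):
    """~1,600-point lattice: cheap but representative."""
    from tifield.grid import sample_grid

    return sample_grid(template_model, 12.0)
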