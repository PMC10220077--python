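import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kmotion import ImageGrid, PhantomConfig, generate_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom64() -> ImageGrid:
    """One deterministic 64x64 head phantom shared across tests."""
    return generate_phantom(PhantomConfig(size=64, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
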