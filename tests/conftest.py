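import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from larvatray import study_containers

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def containers():
    """The three study containers (small circle, medium/large rectangles)."""
    return study_containers()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def uniform_points_in_footprint(container, n, rng):
    """Uniformly random points in a container footprint (geometry oracle)."""
    if container.shape == "rectangle":
        x = rng.uniform(0.0, container.length_cm, n)
        y = rng.uniform(0.0, container.width_cm, n)
    else:
        R = container.diameter_cm / 2.0
        r = R * np.sqrt(rng.uniform(0.0, 1.0, n))
        th = rng.uniform(0.0, 2 * np.pi, n)
        x, y = r * np.cos(th), r * np.sin(th)
    return x, y
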