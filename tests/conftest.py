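import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leechmsi import phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protein_spec():
    return phantom.protein_phantom(seed=1)


@pytest.fixture(scope="session")
def protein_dataset(protein_spec):
    """Default 9-section regenerating-condition phantom (fixed seed)."""
    return phantom.simulate_dataset(protein_spec)


@pytest.fixture(scope="session")
def control_dataset():
    """Same phantom geometry and panel, control condition (no marker)."""
    return phantom.simulate_dataset(phantom.protein_phantom(condition="control", seed=1))


@pytest.fixture(scope="session")
def sinus_dataset():
    """Ganglion core + blood-sinus annulus phantom (disjoint panels)."""
    return phantom.simulate_dataset(phantom.sinus_phantom(seed=1))


@pytest.fixture
def tiny_spec():
    """An 8x8, 2-section, short-axis phantom for I/O and plumbing tests."""
    return phantom.protein_phantom(
        seed=2,
        width=8,
        height=8,
        disc_center=(3.5, 3.5),
        disc_radius=2.5,
        n_sections=2,
        n_points=300,
    )


@pytest.fixture
def tiny_dataset(tiny_spec):
    return phantom.simulate_dataset(tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
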