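import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from rdhybrid.geometry import CellGeometry, discretize_cell
from rdhybrid.model import ReactionNetwork, ReactionSpec, SpeciesSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cell_geometry():
    """The reference cell: 10 um diameter, 3 um concentric nucleus."""
    return CellGeometry(10.0, 3.0)


@pytest.fixture(scope="session")
def cell_lattice(cell_geometry):
    return discretize_cell(cell_geometry, 10)


@pytest.fixture
def decay_network():
    """Single species with a first-order decay channel."""
    return ReactionNetwork(
        [SpeciesSpec("A", 10.0, 0.005)],
        [ReactionSpec(("A",), (), 1.0)],
    )


@pytest.fixture
def ab_network():
    """A + B -> 0 annihilation."""
    return ReactionNetwork(
        [SpeciesSpec("A", 10.0, 0.01), SpeciesSpec("B", 10.0, 0.01)],
        [ReactionSpec(("A", "B"), (), 1e8)],
    )
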