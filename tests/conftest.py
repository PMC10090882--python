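import numpy as np
import pytest

from nasallom.phantom import PhantomSpec, generate_skull_phantom
from nasallom.synthetic import SimulationConfig, simulate_tree


@pytest.fixture(scope="session")
def small_tree():
    """A 10-tip ultrametric tree of depth 100 Ma."""
    return simulate_tree(SimulationConfig(n_tips=10, seed=42))


@pytest.fixture(scope="session")
def default_phantom():
    """Default skull phantom with its landmarks and analytic truths."""
    return generate_skull_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20230412)
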