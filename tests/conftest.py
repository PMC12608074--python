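import numpy as np
import pytest

from argbm import ARG, examples
from argbm.simulate import SimConfig, simulate_arg


@pytest.fixture
def loop_arg():
    """Two samples below a single recombination loop (3 minimal paths)."""
    return examples.two_sample_loop_arg()


@pytest.fixture
def single_loop():
    """Symmetric loop, arm time 2: conditioned Var at the recombination
    node is 1.0, midpoint Var at its upper parent is 1.0."""
    return examples.single_loop_arg(2.0)


@pytest.fixture
def two_tree():
    return examples.two_tree_arg()


@pytest.fixture
def two_tree_locations():
    return np.array([-0.5, 0.0, 0.5, 1.0])


@pytest.fixture
def tree3():
    return examples.three_sample_tree()


def small_sim_arg(seed: int, n_samples: int = 8, L: float = 3e4) -> ARG:
    return simulate_arg(
        SimConfig(n_samples=n_samples, sequence_length=L,
                  recombination_rate=1e-8, population_size=1e4, seed=seed)
    )


@pytest.fixture(scope="session")
def sim_arg():
    """A moderately sized full ARG shared across tests."""
    return small_sim_arg(seed=7, n_samples=10, L=5e4)


@pytest.fixture(scope="session")
def chopped_sim_arg(sim_arg):
    times = sim_arg.node_times
    cut = float(np.quantile(times[times > 0], 0.6)) + 0.5
    return sim_arg.chop(cut)
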