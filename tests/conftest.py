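import numpy as np
import pytest

from dlmra import (
    EstimationOptions,
    generate_design_data,
    make_single_activator,
)


@pytest.fixture(scope="session")
def single_activator():
    return make_single_activator()


@pytest.fixture(scope="session")
def grid11():
    return np.linspace(0.0, 10.0, 11)


@pytest.fixture(scope="session")
def activator_dataset(single_activator, grid11):
    """Clean 11-point complete-inhibition design from the single-activator model."""
    return generate_design_data(single_activator, grid11, p=0.0)


@pytest.fixture(scope="session")
def activator_fit(activator_dataset):
    """Session-wide best fit of the single-activator dataset (reused by
    several tests to keep the suite fast)."""
    from dlmra import fit

    return fit(activator_dataset, EstimationOptions(n_starts=10, seed=42))


def random_stable_nets(n, count, seed):
    from dlmra import sample_random_network

    rng = np.random.default_rng(seed)
    return [sample_random_network(n, rng) for _ in range(count)]
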