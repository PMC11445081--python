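import numpy as np
import pandas as pd
import pytest

from neostate.simulate import CommunityConfig, simulate_states_counts


@pytest.fixture(scope="session")
def small_mixture():
    """A small, well-separated 3-state community draw with planted truth."""
    cfg = CommunityConfig(n_samples=60, n_species=8, depth=2000)
    counts, abundance, truth = simulate_states_counts(cfg, seed=11)
    return counts, abundance, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_simplex(rng, n, s):
    x = rng.dirichlet(np.ones(s), size=n)
    return x / x.sum(axis=1, keepdims=True)


@pytest.fixture()
def simplex_rows(rng):
    return random_simplex(rng, 12, 5)
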