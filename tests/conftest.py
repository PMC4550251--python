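import numpy as np
import pytest

import asymgames as ag


@pytest.fixture(scope="session")
def graph30():
    """Connected random 3-regular graph on 30 vertices."""
    return ag.random_regular_graph(30, 3, seed=1)


@pytest.fixture(scope="session")
def gauss_traits(graph30):
    return ag.assign_traits(graph30, ag.GaussianTraits(3.5, 1.0, 0.5, 0.25), seed=2)


@pytest.fixture(scope="session")
def donation30(graph30, gauss_traits):
    return ag.donation_field(gauss_traits, graph30)


@pytest.fixture(scope="session")
def mixed_state30(graph30):
    """Alternating C/D strategies on the 30-vertex graph."""
    return ag.PopulationState(np.arange(30) % 2, 2)


@pytest.fixture(scope="session")
def k4():
    """The complete graph K4 — the unique 3-regular graph on 4 vertices."""
    return ag.random_regular_graph(4, 3, seed=0)


ALL_RULES = (ag.DEATH_BIRTH, ag.BIRTH_DEATH, ag.IMITATION, ag.PAIRWISE_COMPARISON)
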