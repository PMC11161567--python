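import numpy as np
import pytest

from islandrad import synthetic
from islandrad.biogeo import AreaSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_tree():
    """Factory for seeded ultrametric birth-death trees."""
    def make(n_tips: int, seed: int, birth: float = 1.0, death: float = 0.0):
        return synthetic.sim_tree(n_tips, birth, death, seed=seed)
    return make


@pytest.fixture
def two_area_system():
    return AreaSystem(("A", "B"), np.array([[0.0, 400.0], [400.0, 0.0]]))


@pytest.fixture
def five_area_system():
    n = 5
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 300.0 * abs(i - j)
    return AreaSystem(tuple("ABCDE"), dist)


@pytest.fixture
def planted_scenario():
    return synthetic.planted_survey_scenario(seed=0)
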