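import numpy as np
import pytest

from polygs.simdata import PopulationSpec, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """300 individuals x 500 markers, 50 QTL, h2 = 0.5, fixed seed."""
    spec = PopulationSpec(n_individuals=300, n_markers=500, n_qtl=50, h2=0.5, seed=11)
    return simulate_population(spec)


@pytest.fixture(scope="session")
def toy_matrix():
    rng = np.random.default_rng(0)
    G = rng.integers(0, 3, size=(20, 50)).astype(float)
    beta = np.zeros(50)
    beta[:5] = [1.5, -1.0, 0.8, -0.5, 1.2]
    y = G @ beta + rng.normal(scale=0.5, size=20)
    return G, y
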