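import numpy as np
import pytest

import ddrsim
from ddrsim import EngineConfig
from ddrsim.model import CellState, resting_state


@pytest.fixture(scope="session")
def spec():
    return ddrsim.build_default_model()


@pytest.fixture(scope="session")
def rest(spec):
    """Cached wild-type resting state (y, gene means, dsb mean)."""
    return resting_state(spec)


@pytest.fixture(scope="session")
def rest_state(spec, rest):
    y, g, d = rest
    return CellState(t=0.0, y=y.copy(),
                     genes={gd.name: int(round(gv))
                            for gd, gv in zip(spec.genes, g)},
                     dsb=int(round(d)), receptors_active=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_states(spec, n, seed=0, scale=1e4):
    """Random admissible cell states for property tests."""
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(n):
        y = rng.uniform(0.0, scale, size=spec.n_species)
        genes = {g.name: int(rng.integers(0, 3)) for g in spec.genes}
        states.append(CellState(t=0.0, y=y, genes=genes,
                                dsb=int(rng.integers(0, 300)),
                                receptors_active=int(rng.integers(0, 200))))
    return states
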