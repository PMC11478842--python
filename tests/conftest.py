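import numpy as np
import pytest

from plastomarker.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def compact_dataset():
    """One desk-scale simulated plastome family shared across tests."""
    return simulate(SimulationConfig.compact(seed=11))


@pytest.fixture(scope="session")
def expansion_dataset():
    """Family in which one species carries a 1.2 kb IR expansion."""
    return simulate(
        SimulationConfig.compact(seed=3, ir_expansion=("P_maritima", 1200))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
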