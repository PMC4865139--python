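import pytest

from dgscan.energy import nn_model, pairmax_model
from dgscan.engines import BuiltinEngine


@pytest.fixture(scope="session")
def pm_model():
    return pairmax_model()


@pytest.fixture(scope="session")
def pm_unit_model():
    """PAIRMAX with -1 kcal/mol for every pair class (pair counting)."""
    return pairmax_model(pair_weights={p: -1.0 for p in ("AU", "UA", "CG", "GC", "GU", "UG")})


@pytest.fixture(scope="session")
def nn():
    return nn_model()


@pytest.fixture(scope="session")
def nn_engine(nn):
    """One shared caching NN engine: mutants recur across tests."""
    return BuiltinEngine(nn)
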