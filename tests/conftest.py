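import numpy as np
import pytest
from hypothesis import settings

from lastmile.population_core import IslandState, LifeHistoryParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def big_K_params():
    """Rates with an effectively unlimited carrying capacity, so density
    dependence is switched off in micro-world tests."""
    return LifeHistoryParams(K=1e9)


def make_state(dims=(16, 16), seed=0):
    return IslandState(dims, seed)


def add_individuals(
    state,
    n,
    *,
    sex,
    patch,
    geno=0,
    age=1,
    sterile=False,
    origin=0,
    fresh=False,
):
    """Append ``n`` identical individuals to a state (flat patch index)."""
    return state.add(
        sex=np.full(n, sex, dtype=np.int8),
        age=np.full(n, age, dtype=np.int32),
        patch=np.full(n, patch, dtype=np.int64),
        geno=np.full(n, geno, dtype=np.int8),
        origin=np.full(n, origin, dtype=np.int8),
        sterile=np.full(n, sterile, dtype=bool),
        fresh=np.full(n, fresh, dtype=bool),
    )


@pytest.fixture
def make_island():
    return make_state


@pytest.fixture
def add():
    return add_individuals
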