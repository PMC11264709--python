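"""Shared fixtures: toy models with known steady states and cached burn-ins."""
import numpy as np
import pytest

from pathway_evolver import SelectionTarget, initialize_population
from pathway_evolver.equilibration import EquilibrationConfig, equilibrate_root
from pathway_evolver.fixtures import (
    make_branched_fixture,
    make_linear_chain,
    make_reversible_chain,
)

# loose windowed-detection settings so burn-in converges at test scale
FAST_EQ = dict(window_size=20, consecutive_windows=3, slope_tol=5e-3,
               cv_tol=0.05, generation_cap=50_000)


@pytest.fixture
def linear_chain():
    """3-step irreversible MM chain and its closed-form steady state."""
    return make_linear_chain(n=3, v0=1.0, vmax=2.0, km=1.0)


@pytest.fixture
def reversible_chain():
    return make_reversible_chain(n=2)


@pytest.fixture
def branched_model():
    return make_branched_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240718)


@pytest.fixture(scope="session")
def equilibrated_reversible():
    """One shared seeded burn-in on the reversible chain (expensive-ish)."""
    model = make_reversible_chain(n=2)
    rng = np.random.default_rng(7)
    targets = [SelectionTarget("Rdrain", 1.0)]
    state = initialize_population(model, targets, ne=1000, ploidy=2, rng=rng)
    root = equilibrate_root(state, model, EquilibrationConfig(**FAST_EQ), rng)
    return model, targets, root
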