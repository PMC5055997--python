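import numpy as np
import pytest
from hypothesis import strategies as st

from sosa_spsa import (
    ModelParameters,
    PopulationState,
    find_equilibrium,
    load_fhs_config,
    simulate,
)


@pytest.fixture(scope="session")
def fhs_config():
    """The bundled Framingham-rates reference scenario."""
    return load_fhs_config()


@pytest.fixture(scope="session")
def fhs_trajectory(fhs_config):
    """Long-horizon reference trajectory, shared across tests."""
    c = fhs_config
    return simulate(c.params, c.initial, c.N, t_end=c.t_end, n_points=c.n_points)


@pytest.fixture(scope="session")
def fhs_equilibrium(fhs_config):
    c = fhs_config
    return find_equilibrium(c.params, c.initial, c.N)


def rate() -> st.SearchStrategy[float]:
    return st.floats(0.0, 0.3, allow_nan=False)


@st.composite
def valid_params(draw) -> ModelParameters:
    """Random parameter sets respecting l1+l2 <= 1 and m1+m2 <= 1."""
    l1 = draw(rate())
    m1 = draw(rate())
    l2 = draw(st.floats(0.0, min(0.3, 1.0 - l1), allow_nan=False))
    m2 = draw(st.floats(0.0, min(0.3, 1.0 - m1), allow_nan=False))
    return ModelParameters(
        alpha_O=draw(rate()), beta_O=draw(rate()), g_O=draw(rate()),
        alpha_P=draw(rate()), beta_P=draw(rate()), g_P=draw(rate()),
        l1=l1, l2=l2, m1=m1, m2=m2,
    )


@st.composite
def valid_states(draw, N: float = 1000.0) -> PopulationState:
    """Random states on the S+O+P = N simplex."""
    o = draw(st.floats(0.0, 1.0, allow_nan=False))
    p = draw(st.floats(0.0, 1.0 - o, allow_nan=False))
    return PopulationState(S=N * (1.0 - o - p), O=N * o, P=N * p)


def random_valid_params(rng: np.random.Generator) -> ModelParameters:
    """Seeded draw of a valid parameter set (non-hypothesis contexts)."""
    l1, m1 = rng.uniform(0, 0.3, 2)
    l2 = rng.uniform(0, min(0.3, 1 - l1))
    m2 = rng.uniform(0, min(0.3, 1 - m1))
    a_O, b_O, g_O, a_P, b_P, g_P = rng.uniform(0.0, 0.3, 6)
    return ModelParameters(
        alpha_O=a_O, beta_O=b_O, g_O=g_O, alpha_P=a_P, beta_P=b_P, g_P=g_P,
        l1=l1, l2=l2, m1=m1, m2=m2,
    )
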