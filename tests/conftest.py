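import numpy as np
import pytest

from l1agg.grid import FieldState, PeriodicGrid
from l1agg.model import ModelParameters, uniform_steady_state


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default (reference) parameter set, both signals enabled."""
    return ModelParameters()


@pytest.fixture(scope="session")
def params_attractant(params) -> ModelParameters:
    return params.attractant_only()


@pytest.fixture
def line_grid() -> PeriodicGrid:
    return PeriodicGrid.line(1.0, 128)


@pytest.fixture
def square_grid() -> PeriodicGrid:
    return PeriodicGrid.square(1.0, 32)


def uniform_state(rho_bar: float, grid: PeriodicGrid,
                  params: ModelParameters) -> FieldState:
    Ua, Ur = uniform_steady_state(rho_bar, params)
    return FieldState(0.0,
                      np.full(grid.shape, float(rho_bar)),
                      np.full(grid.shape, Ua),
                      np.full(grid.shape, Ur) if params.repellent_enabled else None)


def random_state(rho_bar: float, grid: PeriodicGrid, params: ModelParameters,
                 seed: int = 0, amp: float = 0.3) -> FieldState:
    rng = np.random.default_rng(seed)
    st = uniform_state(rho_bar, grid, params)
    for f in st.fields():
        f *= 1.0 + amp * rng.uniform(-1, 1, size=grid.shape)
    return st
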