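import numpy as np
import pytest

from stemrad import ModelParameters, for_cancer
from stemrad.simulator import SimulationGrid


@pytest.fixture
def prostate() -> ModelParameters:
    return for_cancer("prostate")


@pytest.fixture
def lung() -> ModelParameters:
    return for_cancer("lung")


@pytest.fixture
def breast() -> ModelParameters:
    return for_cancer("breast")


@pytest.fixture
def oscillatory() -> ModelParameters:
    """Synthetic slow-turnover parameter set with a genuine delay-induced
    Hopf bifurcation at its exact equilibrium (used to exercise the
    oscillatory regime, which the published cancer sets never reach)."""
    return ModelParameters(q0=10.0, d=5.0, sigma=0.02)


@pytest.fixture
def small_grid() -> SimulationGrid:
    return SimulationGrid(L=100.0, nx=48, ny=48)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240304)
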