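import numpy as np
import pytest

from wbnet import (
    ConnectomeMatrix,
    CoupledSystem,
    SimulationConfig,
    WendlingParams,
)


@pytest.fixture(scope="session")
def params() -> WendlingParams:
    return WendlingParams()


@pytest.fixture(scope="session")
def single_node_system(params) -> CoupledSystem:
    """One uncoupled region."""
    sc = ConnectomeMatrix(np.zeros((1, 1)), ("LH.R001",))
    return CoupledSystem(params=params, connectome=sc, c_global=0.0)


@pytest.fixture(scope="session")
def small_connectome() -> ConnectomeMatrix:
    """Dense symmetric 4-region connectome with max weight 1."""
    w = np.array(
        [
            [0.0, 1.0, 0.4, 0.2],
            [1.0, 0.0, 0.7, 0.1],
            [0.4, 0.7, 0.0, 0.5],
            [0.2, 0.1, 0.5, 0.0],
        ]
    )
    return ConnectomeMatrix(w)


@pytest.fixture()
def short_config() -> SimulationConfig:
    """Cheap protocol for unit tests: 0.6 s simulated, 0.3 s retained."""
    return SimulationConfig(duration=0.6, transient=0.3, n_reps=2, seed=1234)
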