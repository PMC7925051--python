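import numpy as np
import pytest

from qifmf.model_core import ModelParams, StimulusProtocol


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Default model constants."""
    return ModelParams()


@pytest.fixture(scope="session")
def decoupled_params() -> ModelParams:
    """Synapses off: two independent heterogeneous QIF populations."""
    return ModelParams(J_e=0.0, J_i=0.0)


@pytest.fixture(scope="session")
def quiescent_state(params):
    """The unique stable equilibrium at (I_ext, J_e) = (0, 15)."""
    from qifmf import equilibria as eq

    eqs = eq.find_equilibria(params, 0.0, n_starts=256, seed=11)
    assert len(eqs) == 1
    return eqs[0]


@pytest.fixture(scope="session")
def bistable_equilibria(params):
    """All equilibria at the bistable point (I_ext, J_e) = (-3, 32)."""
    from qifmf import equilibria as eq

    return eq.find_equilibria(params.with_(J_e=32.0), -3.0, n_starts=1024, seed=11)


def constant_protocol(I, T):
    return StimulusProtocol.constant(I, T)
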