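"""qifmf: exact mean-field reduction and bifurcation analysis of E-I QIF networks.

The package simulates a two-population (excitatory/inhibitory) network of
quadratic integrate-and-fire neurons with instantaneous conductance synapses
and Lorentzian-distributed background currents, together with its exact
four-dimensional mean-field reduction for the population firing rates and
mean membrane potentials.  Analysis layers locate equilibria, classify
periodic orbits, trace fold / Hopf / period-doubling bifurcation curves in
the (I_ext, J_e) plane, and diagnose the period-doubling route to chaos.
"""

from .mean_field import MeanFieldState, Trajectory, integrate, rhs, synaptic_gate
from .model_core import ModelParams, StimulusProtocol

__version__ = "0.1.0"

__all__ = [
    "ModelParams",
    "StimulusProtocol",
    "MeanFieldState",
    "Trajectory",
    "integrate",
    "rhs",
    "synaptic_gate",
    "__version__",
]


def __getattr__(name):
    # heavy analysis layers are imported lazily
    if name in ("equilibria", "network", "orbits", "continuation",
                "protocols", "analysis", "cli_io"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
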