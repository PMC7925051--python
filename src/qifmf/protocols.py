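"""Stimulus protocols, named parameter points, and synthetic test fixtures.

This module is the package's data generator: the study has no external
data, so every experiment is defined by a parameter point (I_ext, J_e), a
piecewise-constant stimulus protocol, and an expected dynamical outcome.

The catalogue covers the full dynamical repertoire of the model on the
(I_ext, J_e) plane: quiescence, steady high-rate focus, period-1/2/4
synchronization, bistability between a low-rate state and either a focus or
a limit cycle, and chaos at the end of the period-doubling cascade.  Each
entry's ``expected`` tag is a machine-checkable statement of the regime the
model exhibits there, verified by the test suite; a mismatch is a test
failure, not a relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import InvalidParameterError, ModelParams, StimulusProtocol

__all__ = [
    "NamedExperiment",
    "figure1_protocol",
    "bistability_protocol",
    "paper_points",
    "get_experiment",
    "fixture_signal",
]


@dataclass(frozen=True)
class NamedExperiment:
    """A labeled experiment: parameter point, protocol, expected regime."""

    label: str
    I_ext: float
    J_e: float
    protocol: StimulusProtocol
    expected: str          # quiescent | period-1 | focus | period-2 | period-4
    #                      | bistable-node-focus | bistable-node-cycle | chaotic
    needs_pulse: bool = False   # reach the non-quiescent attractor via the pulse

    def params(self, base: ModelParams | None = None) -> ModelParams:
        base = base or ModelParams()
        return base.with_(J_e=self.J_e)


def figure1_protocol(duration: float = 10.0) -> StimulusProtocol:
    """Step protocol of the network/mean-field comparison experiment.

    No drive for the first 2 time units (quiescence), then a step to
    I_ext = 8 that synchronizes the network.
    """
    return StimulusProtocol.from_steps([0.0, 8.0], [2.0], duration)


def bistability_protocol(
    base: float = -3.0, pulse: float = 3.0, duration: float = 25.0
) -> StimulusProtocol:
    """Transient-switch protocol: base drive with a pulse on t in [10, 12).

    The pulse kicks the system out of the quiescent basin; after it ends
    the trajectory relaxes onto the coexisting attractor (focus or limit
    cycle), demonstrating bistability.
    """
    if duration <= 12.0:
        raise InvalidParameterError("bistability protocol needs duration > 12")
    if base == pulse:
        return StimulusProtocol.constant(base, duration)
    return StimulusProtocol.from_steps([base, pulse, base], [10.0, 12.0], duration)


def paper_points() -> list[NamedExperiment]:
    """The labeled catalogue of study points in the (I_ext, J_e) plane.

    Coordinates follow the source study's figure points; the expected tag is
    the regime of this model (the exact reduction) at that point, verified
    by the test suite.  Points labeled ``cascade-*`` pin the period-doubling
    route along the I_ext = -3 line, which in this model unfolds at
    J_e ~ 55-66 (the coupling axis of the cascade is stretched relative to
    the source figures; the ordering 1 -> 2 -> 4 -> chaos is the invariant).
    """
    const = StimulusProtocol.constant
    pts = [
        NamedExperiment("fig1-pre", 0.0, 15.0, const(0.0, 10.0), "quiescent"),
        NamedExperiment("fig1", 8.0, 15.0, figure1_protocol(), "period-1"),
        NamedExperiment("fig4a", 5.0, 30.0, const(5.0, 60.0), "focus"),
        NamedExperiment("fig4b", 5.0, 50.0, const(5.0, 60.0), "period-1"),
        NamedExperiment("fig4c", 0.0, 70.0, const(0.0, 60.0), "period-1"),
        NamedExperiment("fig4d", -0.85, 75.0, const(-0.85, 60.0), "period-1"),
        NamedExperiment("fig6a", -3.0, 32.0, bistability_protocol(),
                        "bistable-node-focus", needs_pulse=True),
        NamedExperiment("fig6b", -3.0, 45.0, bistability_protocol(),
                        "bistable-node-cycle", needs_pulse=True),
        NamedExperiment("fig6c", -3.0, 51.0, bistability_protocol(),
                        "bistable-node-cycle", needs_pulse=True),
        NamedExperiment("fig6d", -3.0, 52.4, bistability_protocol(),
                        "bistable-node-cycle", needs_pulse=True),
        NamedExperiment("fig7b", -3.0, 53.5, bistability_protocol(),
                        "bistable-node-cycle", needs_pulse=True),
        NamedExperiment("cascade-p1", -3.0, 50.0, bistability_protocol(),
                        "period-1", needs_pulse=True),
        NamedExperiment("cascade-p2", -3.0, 58.0, bistability_protocol(),
                        "period-2", needs_pulse=True),
        NamedExperiment("cascade-p4", -3.0, 63.0, bistability_protocol(),
                        "period-4", needs_pulse=True),
        # beyond the upper fold the quiescent state is gone; the chaotic
        # attractor is reached from any initial condition
        NamedExperiment("chaos", -3.0, 66.0, const(-3.0, 25.0), "chaotic"),
    ]
    labels = [e.label for e in pts]
    assert len(labels) == len(set(labels))
    return pts


def get_experiment(label: str) -> NamedExperiment:
    for e in paper_points():
        if e.label == label:
            return e
    raise InvalidParameterError(f"unknown experiment label {label!r}")


def fixture_signal(kind: str, seed: int = 0, **kw):
    """Synthetic traces/rasters with known ground truth, for unit tests.

    kinds
    -----
    sinusoid
        ``x = offset + amp*sin(2 pi t / period)``; true period class 1.
    alternating_peaks
        Peak train with amplitudes alternating high/low; true class 2.
    period4_peaks
        Peak train repeating a 4-amplitude motif; true class 4.
    poisson_raster
        Homogeneous Poisson spikes for N neurons at rate lam over [0, T];
        expected total count N*lam*T.

    Returns (t, x) for traces and a dict with 'times'/'neuron' for rasters,
    plus the ground truth under key/attr conventions documented per kind.
    """
    rng = np.random.default_rng(seed)
    if kind == "sinusoid":
        period = kw.get("period", 2 * math.pi)
        amp = kw.get("amp", 1.0)
        offset = kw.get("offset", 2.0)
        dt = kw.get("dt", 0.01)
        n_cycles = kw.get("n_cycles", 12)
        t = np.arange(0.0, n_cycles * period, dt)
        return t, offset + amp * np.sin(2 * math.pi * t / period), {"period_class": 1}
    if kind in ("alternating_peaks", "period4_peaks"):
        motif = [1.0, 0.5] if kind == "alternating_peaks" else [1.0, 0.7, 0.9, 0.4]
        n_motifs = kw.get("n_motifs", 8)
        spacing = kw.get("spacing", 1.0)
        width = kw.get("width", 0.15)
        dt = kw.get("dt", 0.005)
        amps = np.tile(motif, n_motifs)
        centers = spacing * (1 + np.arange(amps.size))
        t = np.arange(0.0, centers[-1] + spacing, dt)
        x = np.zeros_like(t)
        for c, a in zip(centers, amps):
            x += a * np.exp(-0.5 * ((t - c) / width) ** 2)
        return t, x, {"period_class": len(motif)}
    if kind == "poisson_raster":
        lam = kw.get("lam", 0.2)
        N = kw.get("N", 100)
        T = kw.get("T", 100.0)
        counts = rng.poisson(lam * T, size=N)
        tt = np.concatenate([rng.uniform(0, T, c) for c in counts]) if N else np.empty(0)
        nn = np.concatenate([np.full(c, i) for i, c in enumerate(counts)]) if N else np.empty(0)
        order = np.argsort(tt)
        return {"times": tt[order], "neuron": nn[order].astype(int),
                "N": N, "T": T, "rate": lam}
    raise InvalidParameterError(f"unknown fixture kind {kind!r}")
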