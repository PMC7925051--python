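"""Shared model constants, stimulus protocols, and Lorentzian heterogeneity utilities.

The network draws each neuron's constant background current eta from a
Lorentzian (Cauchy) density g(eta); the heavy tails and the pole structure of
that density are what make the exact mean-field reduction possible, so no
other heterogeneity distribution is supported.

All quantities are in dimensionless model units.  Times and rates are quoted
in the "s"/"Hz" vocabulary used when plotting, with one model time unit
playing the role of one second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "StimulusProtocol",
    "lorentzian_pdf",
    "lorentzian_cdf",
    "lorentzian_quantiles",
    "lorentzian_sample",
]


class InvalidParameterError(ValueError):
    """A model or operation parameter violates its contract."""


@dataclass(frozen=True)
class ModelParams:
    """Constants of the two-population QIF network and its mean-field reduction.

    Parameters
    ----------
    J_e, J_i
        Excitatory and inhibitory synaptic conductances (dimensionless).
    E_e, E_i
        Excitatory and inhibitory reversal potentials.
    eta_bar, delta
        Center and half-width of the Lorentzian density of per-neuron
        background currents; ``delta`` must be positive.
    V_th
        Voltage threshold of the instantaneous synaptic gate: a neuron
        contributes to its population's synaptic activation while V > V_th.
    V_peak, V_reset
        Finite spike-detection and reset voltages used by the spiking
        network only (the idealized model sends both to infinity; the
        symmetric convention V_reset = -V_peak is enforced).  The mean-field
        equations do not depend on them.
    gate_convention
        How the mean-field synaptic gate maps (r, v) to the above-threshold
        fraction.  ``"exact"`` (default) uses the Lorentzian half-width
        pi*r, S = 1/2 - arctan((V_th - v)/(pi r))/pi, which is the residue
        evaluation of the Heaviside integral; ``"narrow"`` uses r in place
        of pi*r (a pi-fold narrower density, kept for sensitivity checks).
    rate_coupling
        Conductance terms carried by the mean-field rate equations.
        ``"full"`` (default) damps each rate by the population's total
        synaptic conductance r (J_e S_e + J_i S_i), as follows from the
        pole motion of the Lorentzian density under the conductance flow;
        ``"self"`` keeps only the population's own recurrent term (a
        truncated variant kept for sensitivity checks).
    """

    J_e: float = 15.0
    J_i: float = 8.0
    E_e: float = 75.0
    E_i: float = -75.0
    eta_bar: float = -5.0
    delta: float = 1.0
    V_th: float = 50.0
    V_peak: float = 500.0
    V_reset: float = -500.0
    gate_convention: str = "exact"
    rate_coupling: str = "full"

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise InvalidParameterError(f"delta must be > 0, got {self.delta}")
        if self.gate_convention not in ("exact", "narrow"):
            raise InvalidParameterError(
                f"gate_convention must be 'exact' or 'narrow', got {self.gate_convention!r}"
            )
        if self.rate_coupling not in ("full", "self"):
            raise InvalidParameterError(
                f"rate_coupling must be 'full' or 'self', got {self.rate_coupling!r}"
            )
        if self.V_reset != -self.V_peak:
            raise InvalidParameterError(
                f"V_reset must equal -V_peak, got V_peak={self.V_peak}, "
                f"V_reset={self.V_reset}"
            )
        if not (self.E_i < self.V_th < self.E_e):
            raise InvalidParameterError(
                f"require E_i < V_th < E_e, got E_i={self.E_i}, "
                f"V_th={self.V_th}, E_e={self.E_e}"
            )

    def with_(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant external current I_ext(t).

    ``segments`` is an ordered tuple of ``(t_start, t_end, I_ext)`` covering
    ``[0, duration]`` contiguously with no overlaps.  The stimulus is applied
    to the excitatory population only.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(v)) for a, b, v in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise InvalidParameterError("protocol needs at least one segment")
        if abs(segs[0][0]) > 1e-12:
            raise InvalidParameterError("first segment must start at t = 0")
        for (a, b, _) in segs:
            if not b > a:
                raise InvalidParameterError(f"empty or reversed segment ({a}, {b})")
        for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if abs(b0 - a1) > 1e-12:
                raise InvalidParameterError("segments must be contiguous")

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    @classmethod
    def constant(cls, I_ext: float, duration: float) -> "StimulusProtocol":
        return cls(((0.0, duration, I_ext),))

    @classmethod
    def from_steps(
        cls, values: Sequence[float], times: Sequence[float], duration: float
    ) -> "StimulusProtocol":
        """Build from step values and the times at which they switch.

        ``values[0]`` holds on ``[0, times[0])``, ``values[1]`` on
        ``[times[0], times[1])`` and so on until ``duration``.
        """
        if len(values) != len(times) + 1:
            raise InvalidParameterError("need exactly one more value than switch time")
        bounds = [0.0, *times, duration]
        return cls(tuple((bounds[i], bounds[i + 1], values[i]) for i in range(len(values))))

    def value_at(self, t: float) -> float:
        """I_ext at time ``t`` (right-continuous; clamped at the final value)."""
        for a, b, v in self.segments:
            if a <= t < b:
                return v
        if abs(t - self.duration) <= 1e-12:
            return self.segments[-1][2]
        raise InvalidParameterError(f"t={t} outside protocol [0, {self.duration}]")


# ---------------------------------------------------------------------------
# Lorentzian distribution


def _check_delta(delta: float) -> None:
    if not delta > 0:
        raise InvalidParameterError(f"delta must be > 0, got {delta}")


def lorentzian_pdf(eta, eta_bar: float, delta: float):
    """Density of the Lorentzian (Cauchy) distribution.

    g(eta) = (1/pi) * delta / ((eta - eta_bar)^2 + delta^2)
    """
    _check_delta(delta)
    eta = np.asarray(eta, dtype=float)
    out = delta / (math.pi * ((eta - eta_bar) ** 2 + delta**2))
    return out if out.ndim else float(out)


def lorentzian_cdf(eta, eta_bar: float, delta: float):
    """Closed-form CDF: 1/2 + arctan((eta - eta_bar)/delta)/pi."""
    _check_delta(delta)
    eta = np.asarray(eta, dtype=float)
    out = 0.5 + np.arctan((eta - eta_bar) / delta) / math.pi
    return out if out.ndim else float(out)


def lorentzian_quantiles(eta_bar: float, delta: float, n: int) -> np.ndarray:
    """Deterministic quantile grid of the Lorentzian distribution.

    Returns eta_j = eta_bar + delta * tan(pi (2j - n - 1) / (2 (n + 1))) for
    j = 1..n, i.e. the j/(n+1) quantiles.  Used to assign quenched
    heterogeneity in finite networks with minimal sampling noise: the
    empirical CDF of the output tracks the Lorentzian CDF within 2/(n+1).
    """
    _check_delta(delta)
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    j = np.arange(1, n + 1, dtype=float)
    return eta_bar + delta * np.tan(math.pi * (2 * j - n - 1) / (2 * (n + 1)))


def lorentzian_sample(
    eta_bar: float, delta: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """I.i.d. Lorentzian draws via the inverse CDF, reproducible given seed."""
    _check_delta(delta)
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return eta_bar + delta * np.tan(math.pi * (u - 0.5))
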