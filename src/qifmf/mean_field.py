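"""Exact mean-field model of the two-population QIF network.

In the infinite-size limit, under the Lorentzian ansatz for the voltage
density, each population is exactly described by its firing rate r and mean
membrane potential v.  The closed system for (r_e, v_e, r_i, v_i) is

    dr_e/dt = Delta/pi + 2 r_e v_e - J_e r_e S_e
    dv_e/dt = eta_bar + v_e^2 - pi^2 r_e^2
              - J_e (v_e - E_e) S_e - J_i (v_e - E_i) S_i + I_ext
    dr_i/dt = Delta/pi + 2 r_i v_i - J_i r_i S_i
    dv_i/dt = eta_bar + v_i^2 - pi^2 r_i^2
              - J_e (v_i - E_e) S_e - J_i (v_i - E_i) S_i

with the synaptic gates S_k = (1/pi) (pi/2 - arctan((V_th - v_k)/(pi r_k))),
the fraction of population k instantaneously above the gating threshold when
its voltage density is Lorentzian with half-width pi*r_k and center v_k.

Both the gate convention and the conductance terms kept in the rate
equations are selectable on ``ModelParams`` (``gate_convention``,
``rate_coupling``); the defaults are the exact reduction, and truncated
variants are available for sensitivity checks.

Integration is classical fixed-step RK4 with dt = 0.01 by default; the
external drive I_ext is piecewise constant and enters the excitatory voltage
equation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import InvalidParameterError, ModelParams, StimulusProtocol

__all__ = [
    "MeanFieldState",
    "Trajectory",
    "DivergenceError",
    "synaptic_gate",
    "rhs",
    "integrate",
    "compare_to_network",
]

_BLOWUP = 1.0e9


class DivergenceError(RuntimeError):
    """A trajectory component exceeded the blow-up guard."""


@dataclass(frozen=True)
class MeanFieldState:
    """State vector (r_e, v_e, r_i, v_i) of the mean-field system."""

    r_e: float
    v_e: float
    r_i: float
    v_i: float

    def to_array(self) -> np.ndarray:
        return np.array([self.r_e, self.v_e, self.r_i, self.v_i], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "MeanFieldState":
        r_e, v_e, r_i, v_i = (float(x) for x in y)
        return cls(r_e, v_e, r_i, v_i)


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid mean-field trajectory with the applied stimulus."""

    t: np.ndarray          # shape (n,)
    y: np.ndarray          # shape (n, 4): columns r_e, v_e, r_i, v_i
    I_ext: np.ndarray      # shape (n,)

    @property
    def r_e(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def v_e(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def r_i(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def v_i(self) -> np.ndarray:
        return self.y[:, 3]

    @property
    def final_state(self) -> MeanFieldState:
        return MeanFieldState.from_array(self.y[-1])

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        m = (self.t >= t_min) & (self.t <= t_max)
        return Trajectory(self.t[m], self.y[m], self.I_ext[m])

    def to_frame(self, params: ModelParams | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "t": self.t,
                "r_e": self.r_e,
                "v_e": self.v_e,
                "r_i": self.r_i,
                "v_i": self.v_i,
                "I_ext": self.I_ext,
            }
        )
        if params is not None:
            conv = params.gate_convention
            df["S_e"] = [synaptic_gate(r, v, params.V_th, conv)
                         for r, v in zip(self.r_e, self.v_e)]
            df["S_i"] = [synaptic_gate(r, v, params.V_th, conv)
                         for r, v in zip(self.r_i, self.v_i)]
        return df


def synaptic_gate(r: float, v: float, V_th: float, convention: str = "exact") -> float:
    """Fraction of a Lorentzian voltage density lying above V_th.

    With the exact convention the density has half-width pi*r, so
    S = (1/pi) (pi/2 - arctan((V_th - v)/(pi r))) = (1/pi) arg((V_th - v) + i pi r)
    for r > 0; the ``"narrow"`` convention replaces pi*r by r.  At r = 0 the
    one-sided limit is used (0, 1, or 1/2 for v below, above, at threshold)
    so the vector field is defined on the closed half-space r >= 0.
    """
    if r < 0:
        raise InvalidParameterError(f"rate must be >= 0, got {r}")
    if r == 0.0:
        if v < V_th:
            return 0.0
        if v > V_th:
            return 1.0
        return 0.5
    s = math.pi if convention == "exact" else 1.0
    return 0.5 - math.atan((V_th - v) / (s * r)) / math.pi


def _rhs_scalar(re, ve, ri, vi, I_ext, Je, Ji, Ee, Ei, eta, delta, Vth, gs, full):
    """Scalar right-hand side; hot path for the fixed-step integrators.

    ``gs`` is the gate half-width scale (pi for the exact convention),
    ``full`` selects the full conductance damping in the rate equations.
    """
    if re > 0.0:
        Se = 0.5 - math.atan((Vth - ve) / (gs * re)) / math.pi
    else:
        Se = 0.0 if ve < Vth else (1.0 if ve > Vth else 0.5)
    if ri > 0.0:
        Si = 0.5 - math.atan((Vth - vi) / (gs * ri)) / math.pi
    else:
        Si = 0.0 if vi < Vth else (1.0 if vi > Vth else 0.5)
    dpi = delta / math.pi
    dre = dpi + 2.0 * re * ve - Je * re * Se
    dri = dpi + 2.0 * ri * vi - Ji * ri * Si
    if full:
        dre -= Ji * re * Si
        dri -= Je * ri * Se
    pi2 = math.pi * math.pi
    dve = eta + ve * ve - pi2 * re * re - Je * (ve - Ee) * Se - Ji * (ve - Ei) * Si + I_ext
    dvi = eta + vi * vi - pi2 * ri * ri - Je * (vi - Ee) * Se - Ji * (vi - Ei) * Si
    return dre, dve, dri, dvi


def rhs(
    state: MeanFieldState | Sequence[float],
    params: ModelParams,
    I_ext: float,
) -> np.ndarray:
    """Time derivative of (r_e, v_e, r_i, v_i)."""
    y = state.to_array() if isinstance(state, MeanFieldState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError(f"non-finite state {y}")
    d = _rhs_scalar(y[0], y[1], y[2], y[3], I_ext, *_param_tuple(params))
    return np.array(d, dtype=float)


def _rk4_run(y0, n_steps, dt, I_ext, p, out=None, out_offset=0):
    """RK4 at constant I_ext for n_steps; optionally record into ``out``.

    Returns the final (re, ve, ri, vi) tuple.  Raises DivergenceError if any
    component leaves [-1e9, 1e9].
    """
    Je, Ji, Ee, Ei, eta, delta, Vth, gs, full = p
    re, ve, ri, vi = y0
    h = dt
    h2 = 0.5 * dt
    h6 = dt / 6.0
    f = _rhs_scalar
    for k in range(n_steps):
        a0, a1, a2, a3 = f(re, ve, ri, vi, I_ext, Je, Ji, Ee, Ei, eta, delta, Vth, gs, full)
        b0, b1, b2, b3 = f(re + h2 * a0, ve + h2 * a1, ri + h2 * a2, vi + h2 * a3,
                           I_ext, Je, Ji, Ee, Ei, eta, delta, Vth, gs, full)
        c0, c1, c2, c3 = f(re + h2 * b0, ve + h2 * b1, ri + h2 * b2, vi + h2 * b3,
                           I_ext, Je, Ji, Ee, Ei, eta, delta, Vth, gs, full)
        d0, d1, d2, d3 = f(re + h * c0, ve + h * c1, ri + h * c2, vi + h * c3,
                           I_ext, Je, Ji, Ee, Ei, eta, delta, Vth, gs, full)
        re += h6 * (a0 + 2.0 * (b0 + c0) + d0)
        ve += h6 * (a1 + 2.0 * (b1 + c1) + d1)
        ri += h6 * (a2 + 2.0 * (b2 + c2) + d2)
        vi += h6 * (a3 + 2.0 * (b3 + c3) + d3)
        if not (-_BLOWUP < re < _BLOWUP and -_BLOWUP < ve < _BLOWUP
                and -_BLOWUP < ri < _BLOWUP and -_BLOWUP < vi < _BLOWUP):
            raise DivergenceError(
                f"trajectory blew up at step {k + 1} (state {(re, ve, ri, vi)})"
            )
        if out is not None:
            j = out_offset + k
            out[j, 0] = re
            out[j, 1] = ve
            out[j, 2] = ri
            out[j, 3] = vi
    return re, ve, ri, vi


def _param_tuple(params: ModelParams):
    gs = math.pi if params.gate_convention == "exact" else 1.0
    return (params.J_e, params.J_i, params.E_e, params.E_i,
            params.eta_bar, params.delta, params.V_th,
            gs, params.rate_coupling == "full")


def integrate(
    state0: MeanFieldState | Sequence[float],
    protocol: StimulusProtocol,
    dt: float,
    params: ModelParams,
) -> Trajectory:
    """Integrate the mean-field system over a stimulus protocol.

    Classical RK4 with fixed step ``dt``; each protocol segment is integrated
    with its constant I_ext and segment boundaries are rounded to the nearest
    grid point, so switching times must be (near-)multiples of ``dt``.
    """
    if not dt > 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    y = state0.to_array() if isinstance(state0, MeanFieldState) else np.asarray(state0, float)
    p = _param_tuple(params)

    counts = []
    for a, b, _ in protocol.segments:
        n = round((b - a) / dt)
        if abs(n * dt - (b - a)) > 1e-9 + 1e-6 * dt:
            n = max(1, n)
        counts.append(n)
    n_total = sum(counts)
    out = np.empty((n_total + 1, 4), dtype=float)
    out[0] = y
    I_trace = np.empty(n_total + 1, dtype=float)

    cur = tuple(y)
    offset = 0
    try:
        for (a, b, I_val), n in zip(protocol.segments, counts):
            I_trace[offset:offset + n] = I_val
            cur = _rk4_run(cur, n, dt, I_val, p, out=out, out_offset=offset + 1)
            offset += n
    except DivergenceError as err:
        t_fail = offset * dt
        raise DivergenceError(f"{err} (near t = {t_fail:.3f})") from None
    I_trace[-1] = protocol.segments[-1][2]
    t = np.arange(n_total + 1) * dt
    return Trajectory(t=t, y=out, I_ext=I_trace)


def settle(
    state0,
    params: ModelParams,
    I_ext: float,
    t_settle: float,
    dt: float = 0.01,
) -> MeanFieldState:
    """Integrate at constant I_ext without recording; return the final state."""
    y = state0.to_array() if isinstance(state0, MeanFieldState) else np.asarray(state0, float)
    n = max(1, round(t_settle / dt))
    cur = _rk4_run(tuple(y), n, dt, I_ext, _param_tuple(params))
    return MeanFieldState(*cur)


def compare_to_network(
    mf_t: np.ndarray,
    mf_rate: np.ndarray,
    net_t: np.ndarray,
    net_rate: np.ndarray,
    t_window: tuple[float, float],
) -> dict:
    """Agreement metrics between a mean-field rate trace and a network rate trace.

    Both traces are linearly interpolated onto a common uniform grid over
    ``t_window``.  Returns RMS error, relative error of the time-averaged
    rates, and relative mismatch of the dominant oscillation period
    (peak-to-peak; NaN when either trace has fewer than two peaks).
    """
    lo = max(t_window[0], mf_t[0], net_t[0])
    hi = min(t_window[1], mf_t[-1], net_t[-1])
    if not hi > lo:
        raise InvalidParameterError("traces do not overlap on the requested window")
    grid = np.linspace(lo, hi, 2048)
    a = np.interp(grid, mf_t, mf_rate)
    b = np.interp(grid, net_t, net_rate)
    rms = float(np.sqrt(np.mean((a - b) ** 2)))
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    rel_mean = abs(mean_a - mean_b) / max(abs(mean_a), 1e-12)

    from scipy.signal import find_peaks

    def mean_period(x):
        prom = 0.2 * (np.max(x) - np.min(x))
        if prom <= 0:
            return math.nan
        idx, _ = find_peaks(x, prominence=prom)
        if len(idx) < 2:
            return math.nan
        return float(np.mean(np.diff(grid[idx])))

    pa, pb = mean_period(a), mean_period(b)
    if math.isnan(pa) or math.isnan(pb):
        period_mismatch = math.nan
    else:
        period_mismatch = abs(pa - pb) / pa
    return {
        "rms_error": rms,
        "rel_mean_rate_error": rel_mean,
        "period_mismatch": period_mismatch,
        "mean_rate_a": mean_a,
        "mean_rate_b": mean_b,
    }
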