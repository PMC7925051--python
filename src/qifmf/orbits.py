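"""Periodic-orbit detection, period-n classification, and chaos diagnostics.

The synchronized network states appear in the mean-field system as limit
cycles of the excitatory rate r_e.  A cycle is classified period-n when the
sequence of successive r_e peak amplitudes and inter-peak intervals repeats
with period n (within relative tolerances); a trace whose peak sequence fits
no n <= n_max is labeled chaotic.  The inter-peak-interval sweep over a
coupling range and the largest Lyapunov exponent (two-trajectory Benettin
method) together resolve the period-doubling cascade to chaos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .mean_field import (
    DivergenceError,
    MeanFieldState,
    StimulusProtocol,
    Trajectory,
    _param_tuple,
    _rk4_run,
    integrate,
    settle,
)
from .model_core import InvalidParameterError, ModelParams

__all__ = [
    "Peak",
    "ISISweep",
    "InsufficientDataError",
    "detect_peaks",
    "classify_period",
    "attractor_trace",
    "classify_attractor",
    "isi_bifurcation_sweep",
    "lyapunov_max",
    "poincare_points",
]

#: largest period-n tested before a peak sequence is declared chaotic
N_MAX = 16


class InsufficientDataError(ValueError):
    """Not enough peaks to classify a periodic pattern."""


@dataclass(frozen=True)
class Peak:
    time: float
    amplitude: float


@dataclass(frozen=True)
class ISISweep:
    """Inter-peak intervals of r_e for each value of the swept parameter."""

    parameter: np.ndarray                  # swept values (J_e)
    intervals: list[np.ndarray]            # per value; empty when steady/missing
    diverged: np.ndarray                   # bool per value

    def to_frame(self):
        import pandas as pd

        rows = [
            (p, iv)
            for p, ivs in zip(self.parameter, self.intervals)
            for iv in ivs
        ]
        return pd.DataFrame(rows, columns=["J_e", "interval"])


def _quad_refine(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid peak location by a parabola through three samples."""
    a, b, c = x[i - 1], x[i], x[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0.0:
        return float(t[i]), float(b)
    s = 0.5 * (a - c) / denom
    s = min(max(s, -1.0), 1.0)
    dt = t[i + 1] - t[i]
    return float(t[i] + s * dt), float(b - 0.25 * (a - c) * s)


def detect_peaks(t: np.ndarray, x: np.ndarray, min_prominence: float) -> list[Peak]:
    """Local maxima of a sampled trace with quadratic sub-grid refinement.

    ``min_prominence`` is absolute, in the units of ``x``; peaks flush with
    the array ends are discarded (no refinement stencil there).
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if x.size < 3:
        return []
    idx, _ = find_peaks(x, prominence=min_prominence)
    idx = idx[(idx > 0) & (idx < x.size - 1)]
    return [Peak(*_quad_refine(t, x, i)) for i in idx]


def _is_n_periodic(seq: np.ndarray, n: int, tol: float, scale: float) -> bool:
    if seq.size < 2 * n:
        return False
    return all(float(np.ptp(seq[k::n])) <= tol * scale for k in range(n))


def classify_period(
    peaks: list[Peak],
    amp_tol: float = 0.02,
    interval_tol: float = 0.02,
    n_max: int = N_MAX,
):
    """Smallest n for which peak amplitudes and intervals are n-periodic.

    Returns an integer period class, or the string ``"chaotic"`` when no
    n <= n_max fits.  Tolerances are relative: amplitudes against the mean
    absolute amplitude, intervals against the mean interval.  Requires at
    least 8 peaks (post-transient).
    """
    if len(peaks) < 8:
        raise InsufficientDataError(f"need >= 8 peaks, got {len(peaks)}")
    amps = np.array([p.amplitude for p in peaks])
    times = np.array([p.time for p in peaks])
    ivs = np.diff(times)
    amp_scale = float(np.mean(np.abs(amps)))
    iv_scale = float(np.mean(ivs))
    for n in range(1, n_max + 1):
        if _is_n_periodic(amps, n, amp_tol, amp_scale) and _is_n_periodic(
            ivs, n, interval_tol, iv_scale
        ):
            return n
    return "chaotic"


def attractor_trace(
    params: ModelParams,
    I_ext: float,
    state0,
    dt: float = 0.001,
    t_transient: float = 200.0,
    t_measure: float = 100.0,
) -> Trajectory:
    """Post-transient trajectory at constant drive, for attractor analysis.

    The transient removed is max(t_transient, t_measure), integrated without
    recording; the returned trajectory covers the final ``t_measure``.
    """
    t_skip = max(t_transient, t_measure)
    y = settle(state0, params, I_ext, t_skip, dt)
    return integrate(y, StimulusProtocol.constant(I_ext, t_measure), dt, params)


def classify_attractor(
    params: ModelParams,
    I_ext: float,
    state0,
    dt: float = 0.001,
    t_transient: float = 200.0,
    t_measure: float = 100.0,
    amp_tol: float = 0.02,
    interval_tol: float = 0.02,
):
    """Classify the attractor reached from ``state0`` at constant drive.

    Returns ``("steady", final_state)`` for a fixed point, else
    ``(period_class, final_state)`` with period_class as in classify_period.
    """
    traj = attractor_trace(params, I_ext, state0, dt, t_transient, t_measure)
    x = traj.r_e
    spread = float(x.max() - x.min())
    if spread < 1e-5:
        return "steady", traj.final_state
    peaks = detect_peaks(traj.t, x, min_prominence=0.05 * spread)
    if len(peaks) < 8:
        # a decaying spiral toward a fixed point: oscillation present but
        # far slower than any cycle of this system (periods are < 3 time
        # units, so a true cycle shows >= 20 peaks per measure window)
        return "steady", traj.final_state
    return (
        classify_period(peaks, amp_tol=amp_tol, interval_tol=interval_tol),
        traj.final_state,
    )


def isi_bifurcation_sweep(
    params: ModelParams,
    I_ext: float,
    Je_values: np.ndarray,
    dt: float = 0.001,
    t_transient: float = 200.0,
    t_measure: float = 100.0,
    init_mode: str = "continue",
    state0=None,
    kick: float = 3.0,
) -> ISISweep:
    """Inter-peak intervals of r_e across a range of excitatory coupling.

    For each J_e the system is settled for ``t_transient`` and the intervals
    between successive r_e peaks over ``t_measure`` are recorded.  With
    ``init_mode="continue"`` the initial condition is inherited from the
    previous grid point (branch following through the cascade); with
    ``"fixed"`` every point restarts from ``state0``.  When no starting
    state is supplied, the quiescent equilibrium is pulse-kicked (drive
    I_ext + ``kick`` for 2 time units) onto the oscillatory attractor.
    A diverging grid point is recorded as missing and the sweep continues.
    """
    if init_mode not in ("continue", "fixed"):
        raise InvalidParameterError(f"unknown init_mode {init_mode!r}")
    Je_values = np.asarray(Je_values, float)

    def default_start(p: ModelParams) -> MeanFieldState:
        y = settle(np.array([0.1, -2.0, 0.1, -2.0]), p, I_ext, 20.0, dt)
        return settle(y, p, I_ext + kick, 2.0, dt)

    intervals: list[np.ndarray] = []
    diverged = np.zeros(Je_values.size, dtype=bool)
    carry = None
    for k, Je in enumerate(Je_values):
        p = params.with_(J_e=float(Je))
        if init_mode == "fixed" or carry is None:
            start = state0 if state0 is not None else default_start(p)
        else:
            start = carry
        try:
            traj = attractor_trace(p, I_ext, start, dt, t_transient, t_measure)
        except DivergenceError:
            diverged[k] = True
            intervals.append(np.empty(0))
            carry = None
            continue
        carry = traj.final_state
        x = traj.r_e
        spread = float(x.max() - x.min())
        if spread < 1e-5:
            intervals.append(np.empty(0))
            continue
        peaks = detect_peaks(traj.t, x, min_prominence=0.05 * spread)
        intervals.append(np.diff([p_.time for p_ in peaks]))
    return ISISweep(parameter=Je_values, intervals=intervals, diverged=diverged)


def count_interval_clusters(intervals: np.ndarray, rel_tol: float = 0.02) -> int:
    """Number of distinct inter-peak-interval values, clustered at rel_tol.

    Greedy single-linkage on the sorted intervals: a new cluster opens when
    the gap to the previous value exceeds ``rel_tol`` times the mean
    interval.  The cluster count over a coupling sweep exposes the
    period-doubling cascade (1 -> 2 -> 4 -> ...).
    """
    iv = np.sort(np.asarray(intervals, float))
    if iv.size == 0:
        return 0
    scale = float(np.mean(iv))
    gaps = np.diff(iv)
    return 1 + int(np.count_nonzero(gaps > rel_tol * scale))


def lyapunov_max(
    params: ModelParams,
    I_ext: float,
    J_e: float | None = None,
    t_total: float = 2000.0,
    t_renorm: float = 1.0,
    d0: float = 1e-7,
    seed: int = 0,
    state0=None,
    t_settle: float = 300.0,
    dt: float = 0.001,
) -> float:
    """Largest Lyapunov exponent by the two-trajectory Benettin method.

    A reference trajectory on the attractor and a companion displaced by
    ``d0`` (random direction drawn from ``seed``) are integrated side by
    side; every ``t_renorm`` the log separation growth is accumulated and
    the companion is rescaled back to distance d0.  Returns the average
    log-divergence rate over ``t_total``.
    """
    if t_total < 10 * t_renorm:
        raise InvalidParameterError("t_total must be well above t_renorm")
    p = params if J_e is None else params.with_(J_e=float(J_e))
    pt = _param_tuple(p)
    if state0 is None:
        state0 = np.array([0.1, -2.0, 0.1, -2.0])
    y = settle(state0, p, I_ext, t_settle, dt).to_array()

    rng = np.random.default_rng(seed)
    u = rng.normal(size=4)
    u /= np.linalg.norm(u)
    z = y + d0 * u

    n_seg = int(round(t_total / t_renorm))
    n_steps = max(1, int(round(t_renorm / dt)))
    acc = 0.0
    for _ in range(n_seg):
        y = np.array(_rk4_run(tuple(y), n_steps, dt, I_ext, pt))
        z = np.array(_rk4_run(tuple(z), n_steps, dt, I_ext, pt))
        d = float(np.linalg.norm(z - y))
        if d == 0.0:
            d = 1e-300
        acc += math.log(d / d0)
        z = y + (z - y) * (d0 / d)
    return acc / (n_seg * n_steps * dt)


def poincare_points(traj: Trajectory, level: float | None = None) -> np.ndarray:
    """States at positive-going crossings of r_e through a section level.

    Defaults to the running mean of r_e.  Crossing states are linearly
    interpolated between samples; used to verify that a period-n orbit
    pierces its section in n distinct points.
    """
    x = traj.r_e
    if level is None:
        level = float(np.mean(x))
    below = x[:-1] < level
    above = x[1:] >= level
    idx = np.flatnonzero(below & above)
    pts = []
    for i in idx:
        w = (level - x[i]) / (x[i + 1] - x[i])
        pts.append(traj.y[i] + w * (traj.y[i + 1] - traj.y[i]))
    return np.asarray(pts)
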