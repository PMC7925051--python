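"""High-level orchestration of the two-parameter bifurcation scenario.

Assembles the full (I_ext, J_e) picture from the lower-level continuation
primitives: the fold curve f (one curve through its cusp), the two Hopf
curves h1 (bounding the low-coupling oscillatory tongue) and h2 (loss of
stability of the high-rate focus), and the first two period-doubling curves
PD1 and PD2 of the cascade, then counts the open regions the five curves cut
out of the analysis window.
"""

from __future__ import annotations

import numpy as np

from . import continuation as ct
from . import equilibria as eq
from .model_core import InvalidParameterError, ModelParams

__all__ = ["DEFAULT_WINDOW", "trace_scenario_curves", "two_parameter_scenario"]

#: analysis window (I_ext range, J_e range); encloses every study point
DEFAULT_WINDOW = ((-6.0, 10.0), (5.0, 80.0))


def _fold_and_h2_seeds(params: ModelParams, window):
    """Fold + Hopf seeds from the J_e branch at I_ext = -3 (bistable slice)."""
    es = eq.find_equilibria(params.with_(J_e=15.0), -3.0, n_starts=256, seed=1)
    if not es:
        raise InvalidParameterError("no equilibrium at (I_ext, J_e) = (-3, 15)")
    br = ct.continue_equilibrium(params, "J_e", es[0], 15.0, window[1], I_ext=-3.0)
    folds = [s for s in br.special_points if s.kind == "fold"]
    hopfs = [s for s in br.special_points if s.kind == "hopf"]
    if not folds or not hopfs:
        raise InvalidParameterError("expected fold and Hopf points on the I=-3 slice")
    return folds[0], hopfs[0]


def _h1_seed(params: ModelParams):
    """Hopf seed on the low-coupling boundary of the oscillatory tongue."""
    es = eq.find_equilibria(params.with_(J_e=5.0), 5.0, n_starts=256, seed=1)
    if not es:
        raise InvalidParameterError("no equilibrium at (I_ext, J_e) = (5, 5)")
    br = ct.continue_equilibrium(params.with_(J_e=5.0), "J_e", es[0], 5.0,
                                 (5.0, 30.0), I_ext=5.0)
    hopfs = [s for s in br.special_points if s.kind == "hopf"]
    if not hopfs:
        raise InvalidParameterError("expected a Hopf point on the I=5 slice")
    return hopfs[0]


def _trace_pd(params, label, slices, centers, window, n_periods, span=8.0,
              edge_refine=2, mode="multiplier", lower_curve=None):
    """Assemble a PD curve from multiplier bisection on I_ext slices.

    ``centers`` may give an initial J_e bracket center per slice (scalar ->
    reused, tracking the previous hit afterwards).  Where the curve leaves
    through the top of the window, up to ``edge_refine`` midpoint slices are
    inserted between the last hit and the first miss and the final segment
    is extrapolated to the window boundary so the rasterized curve seals
    against the edge.
    """
    (I_lo, I_hi), (J_lo, J_hi) = window
    center = float(centers)

    def locate(I, lo, hi):
        if mode == "multiplier":
            return ct.find_pd_on_slice(params, float(I), (lo, hi),
                                       n_periods=n_periods, shoot_dt=1e-3)
        return ct.find_period_transition(params, float(I), (lo, hi),
                                         from_class=2 * n_periods)

    # process slices outward from the anchor (the slice nearest I = -3,
    # where the cascade is wide and the oscillatory branch easy to reach),
    # carrying the on-branch state between slices in classification mode
    slices = sorted(float(I) for I in slices)
    anchor = min(range(len(slices)), key=lambda i: abs(slices[i] + 3.0))
    order = sorted(range(len(slices)), key=lambda i: (abs(i - anchor), -i))

    pts: list[tuple[float, float]] = []
    misses: list[float] = []
    centers_by_idx: dict[int, float] = {}
    states_by_idx: dict[int, object] = {}
    for i in order:
        I = slices[i]
        near = [j for j in (i - 1, i + 1) if j in centers_by_idx]
        c = centers_by_idx[near[0]] if near else center
        st = states_by_idx.get(near[0]) if near else None
        lo = max(J_lo, c - span)
        hi = min(J_hi, c + span)
        if lower_curve is not None:
            base = lower_curve.get(round(I, 6))
            if base is not None:
                lo = max(lo, base + 0.75)
                hi = max(min(J_hi, base + 1.5 * span), lo + 1.0)
        if mode == "classification":
            Je, st_out = ct.find_period_transition(
                params, I, (lo, hi), from_class=2 * n_periods,
                state0=st, return_state=True)
        else:
            Je = locate(I, lo, hi)
            st_out = None
        if Je is None:
            misses.append(I)
            continue
        pts.append((I, Je))
        centers_by_idx[i] = Je
        states_by_idx[i] = st_out
    # a missed slice on the window's left edge leaves the curve dangling
    # inside the window; retry it with a wider bracket around the leftmost hit
    if pts and misses and min(misses) < min(p[0] for p in pts):
        I_edge = min(misses)
        cL = min(pts)[1]
        if mode == "classification":
            base = None if lower_curve is None else lower_curve.get(round(I_edge, 6))
            lo = max(J_lo, cL - 1.5 * span) if base is None else base + 0.75
            Je, _ = ct.find_period_transition(
                params, I_edge, (lo, min(J_hi, cL + span)),
                from_class=2 * n_periods, return_state=True)
        else:
            Je = locate(I_edge, max(J_lo, cL - 1.5 * span), min(J_hi, cL + span))
        if Je is not None:
            pts.append((I_edge, Je))
    if not pts:
        raise InvalidParameterError(f"no {label} points found on any slice")

    # refine toward the miss adjacent to the last hit (curve exits the window)
    pts.sort()
    for _ in range(edge_refine):
        hit_Is = [p[0] for p in pts]
        right_miss = min((m for m in misses if m > max(hit_Is)), default=None)
        if right_miss is None:
            break
        I_mid = 0.5 * (max(hit_Is) + right_miss)
        anchor_J = max(pts)[1]
        if mode == "classification":
            Je, _ = ct.find_period_transition(
                params, I_mid, (max(J_lo, anchor_J - span),
                                min(J_hi, anchor_J + 1.5 * span)),
                from_class=2 * n_periods,
                state0=states_by_idx.get(max(centers_by_idx)),
                return_state=True)
        else:
            Je = locate(I_mid, max(J_lo, anchor_J - span),
                        min(J_hi, anchor_J + 1.5 * span))
        if Je is None:
            misses.append(I_mid)
        else:
            pts.append((I_mid, Je))
            pts.sort()

    P = np.array(sorted(pts))
    # extrapolate the steep final segment to the top of the window
    if len(P) >= 2 and P[-1, 1] < J_hi:
        dI = P[-1, 0] - P[-2, 0]
        dJ = P[-1, 1] - P[-2, 1]
        if dJ > 1e-9:
            I_exit = P[-1, 0] + dI / dJ * (J_hi - P[-1, 1])
            if I_exit <= I_hi:
                P = np.vstack([P, [I_exit, J_hi]])
    return ct.BifurcationCurve("period_doubling", label, P)


def _seal_endpoint(curve, other, max_snap=0.5):
    """Snap a curve end onto another curve it analytically terminates on.

    The low-coupling Hopf curve ends at a Bogdanov-Takens point that lies
    exactly on the fold curve; the traced endpoint stops within the omega
    cutoff of it, so the nearest fold point is appended to seal the
    junction for region counting.
    """

    P = curve.points
    for end in (0, -1):
        q = P[end]
        d = np.linalg.norm(other.points - q, axis=1)
        k = int(np.argmin(d))
        if 0 < d[k] <= max_snap:
            snap = other.points[k]
            P = np.vstack([[snap], P]) if end == 0 else np.vstack([P, [snap]])
    return ct.BifurcationCurve(curve.curve_type, curve.label, P)


def trace_scenario_curves(
    params: ModelParams | None = None,
    window=DEFAULT_WINDOW,
    pd_slices: np.ndarray | None = None,
) -> list[ct.BifurcationCurve]:
    """Trace f, h1, h2, PD1 and PD2 over the analysis window."""
    params = params or ModelParams()
    fold_seed, h2_seed = _fold_and_h2_seeds(params, window)
    h1_seed = _h1_seed(params)

    fold = ct.trace_codim2_curve(
        "fold", {"y": fold_seed.y, "I_ext": -3.0, "J_e": fold_seed.param},
        params, window=window, label="f")
    h2 = ct.trace_codim2_curve(
        "hopf", {"y": h2_seed.y, "I_ext": -3.0, "J_e": h2_seed.param,
                 "omega": h2_seed.info["omega"]},
        params, window=window, label="h2")
    h1 = ct.trace_codim2_curve(
        "hopf", {"y": h1_seed.y, "I_ext": 5.0, "J_e": h1_seed.param,
                 "omega": h1_seed.info["omega"]},
        params, window=window, label="h1")
    h1 = _seal_endpoint(h1, fold)

    if pd_slices is None:
        pd_slices = np.array([-6.0, -5.0, -4.0, -3.0, -2.5, -2.0, -1.5])
    pd1 = _trace_pd(params, "PD1", pd_slices, 48.0, window, n_periods=1)
    # the second doubling sits a few units above the first; seed each slice's
    # bracket from the traced PD1 curve
    pd1_of = dict((round(float(I), 6), float(J)) for I, J in pd1.points)
    pd2 = _trace_pd(params, "PD2", pd_slices, 52.0, window, n_periods=1,
                    mode="classification", lower_curve=pd1_of)
    return [fold, h1, h2, pd1, pd2]


def two_parameter_scenario(
    params: ModelParams | None = None,
    window=DEFAULT_WINDOW,
    resolution: int = 400,
    pd_slices: np.ndarray | None = None,
) -> dict:
    """Trace all five curves and count the regions they partition.

    Returns {"curves", "n_regions", "n_regions_refined"}; the refined count
    re-rasterizes at double resolution as a stability check.
    """
    curves = trace_scenario_curves(params, window, pd_slices)
    part = ct.partition_regions(curves, window=window, resolution=resolution,
                                check_refinement=True)
    return {
        "curves": curves,
        "n_regions": part["n_regions"],
        "n_regions_refined": part["n_regions_refined"],
        "labels": part["labels"],
    }
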