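"""Fixed points of the mean-field system and their linear stability.

Equilibria are located by quasi-Newton root finding (Powell hybrid with the
analytic Jacobian) from a low-discrepancy multi-start grid, deduplicated, and
classified from the eigenvalues of the Jacobian.  The classification labels
(stable node / stable focus / saddle / ...) are the vocabulary in which the
two-parameter bifurcation scenario is described: the quiescent network state
is a stable node at low rate, the steady high-rate state a stable focus, and
synchronized states are limit cycles born from Hopf bifurcations of these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .mean_field import MeanFieldState
from .model_core import InvalidParameterError, ModelParams

__all__ = ["Equilibrium", "find_equilibria", "jacobian", "classify", "rhs_array"]

HYPERBOLICITY_TOL = 1.0e-6
RESIDUAL_TOL = 1.0e-9

#: default multi-start search box: (r_e, v_e, r_i, v_i) lower/upper corners
DEFAULT_BOX = ((0.0, -80.0, 0.0, -80.0), (20.0, 80.0, 20.0, 80.0))


@dataclass(frozen=True)
class Equilibrium:
    state: MeanFieldState
    eigenvalues: np.ndarray  # 4 complex numbers
    classification: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.classification in ("stable node", "stable focus")


def rhs_array(y: np.ndarray, params: ModelParams, I_ext: float) -> np.ndarray:
    """Vector field as a plain array function (no r >= 0 guard).

    The arctan gate extends smoothly through r = 0 (odd in r), so Newton
    iterates may cross into r < 0 transiently; such roots are discarded by
    the caller.
    """
    re, ve, ri, vi = y
    gs = math.pi if params.gate_convention == "exact" else 1.0
    Se = _gate_signed(re, ve, params.V_th, gs)
    Si = _gate_signed(ri, vi, params.V_th, gs)
    dpi = params.delta / math.pi
    dre = dpi + 2.0 * re * ve - params.J_e * re * Se
    dri = dpi + 2.0 * ri * vi - params.J_i * ri * Si
    if params.rate_coupling == "full":
        dre -= params.J_i * re * Si
        dri -= params.J_e * ri * Se
    pi2 = math.pi * math.pi
    dve = (params.eta_bar + ve * ve - pi2 * re * re
           - params.J_e * (ve - params.E_e) * Se
           - params.J_i * (ve - params.E_i) * Si + I_ext)
    dvi = (params.eta_bar + vi * vi - pi2 * ri * ri
           - params.J_e * (vi - params.E_e) * Se
           - params.J_i * (vi - params.E_i) * Si)
    return np.array([dre, dve, dri, dvi])


def _gate_signed(r: float, v: float, V_th: float, gs: float) -> float:
    if r == 0.0:
        return 0.0 if v < V_th else (1.0 if v > V_th else 0.5)
    return 0.5 - math.atan((V_th - v) / (gs * r)) / math.pi


def jacobian(state, params: ModelParams, I_ext: float = 0.0) -> np.ndarray:
    """Analytic 4x4 Jacobian of the mean-field vector field.

    Requires r_e, r_i != 0 (the gate is not differentiable at r = 0).
    I_ext is constant and does not enter the Jacobian; it is accepted for
    interface symmetry with the vector field.
    """
    y = state.to_array() if isinstance(state, MeanFieldState) else np.asarray(state, float)
    re, ve, ri, vi = y
    if re == 0.0 or ri == 0.0:
        raise InvalidParameterError("Jacobian undefined at r = 0 (gate kink)")
    Je, Ji = params.J_e, params.J_i
    Ee, Ei, Vth = params.E_e, params.E_i, params.V_th
    gs = math.pi if params.gate_convention == "exact" else 1.0

    Se = _gate_signed(re, ve, Vth, gs)
    Si = _gate_signed(ri, vi, Vth, gs)
    qe = (gs * re) ** 2 + (Vth - ve) ** 2
    qi = (gs * ri) ** 2 + (Vth - vi) ** 2
    dSe_dr = gs * (Vth - ve) / (math.pi * qe)
    dSe_dv = gs * re / (math.pi * qe)
    dSi_dr = gs * (Vth - vi) / (math.pi * qi)
    dSi_dv = gs * ri / (math.pi * qi)
    pi2 = math.pi * math.pi

    J = np.zeros((4, 4))
    # d(dr_e)/d*
    J[0, 0] = 2 * ve - Je * (Se + re * dSe_dr)
    J[0, 1] = 2 * re - Je * re * dSe_dv
    # d(dv_e)/d*
    J[1, 0] = -2 * pi2 * re - Je * (ve - Ee) * dSe_dr
    J[1, 1] = 2 * ve - Je * Se - Je * (ve - Ee) * dSe_dv - Ji * Si
    J[1, 2] = -Ji * (ve - Ei) * dSi_dr
    J[1, 3] = -Ji * (ve - Ei) * dSi_dv
    # d(dr_i)/d*
    J[2, 2] = 2 * vi - Ji * (Si + ri * dSi_dr)
    J[2, 3] = 2 * ri - Ji * ri * dSi_dv
    # d(dv_i)/d*
    J[3, 0] = -Je * (vi - Ee) * dSe_dr
    J[3, 1] = -Je * (vi - Ee) * dSe_dv
    J[3, 2] = -2 * pi2 * ri - Ji * (vi - Ei) * dSi_dr
    J[3, 3] = 2 * vi - Je * Se - Ji * Si - Ji * (vi - Ei) * dSi_dv

    if params.rate_coupling == "full":
        J[0, 0] -= Ji * Si
        J[0, 2] -= Ji * re * dSi_dr
        J[0, 3] -= Ji * re * dSi_dv
        J[2, 2] -= Je * Se
        J[2, 0] -= Je * ri * dSe_dr
        J[2, 1] -= Je * ri * dSe_dv
    return J


def classify(eigenvalues, tol: float = HYPERBOLICITY_TOL) -> str:
    """Stability label from the four Jacobian eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=complex)
    if lam.shape != (4,):
        raise InvalidParameterError("expected exactly 4 eigenvalues")
    re = lam.real
    if np.any(np.abs(re) < tol):
        return "nonhyperbolic"
    has_complex = bool(np.any(np.abs(lam.imag) > tol))
    if np.all(re < 0):
        return "stable focus" if has_complex else "stable node"
    if np.all(re > 0):
        return "unstable focus" if has_complex else "unstable node"
    return "saddle"


def _dedup_key(y: np.ndarray) -> np.ndarray:
    # rates scaled x10 so the metric balances rate and voltage magnitudes
    return y * np.array([10.0, 1.0, 10.0, 1.0])


def make_equilibrium(y: np.ndarray, params: ModelParams, I_ext: float) -> Equilibrium:
    """Attach residual, eigenvalues, and classification to a root."""
    res = float(np.linalg.norm(rhs_array(y, params, I_ext)))
    lam = np.linalg.eigvals(jacobian(y, params, I_ext))
    order = np.argsort(-lam.real)
    lam = lam[order]
    return Equilibrium(
        state=MeanFieldState.from_array(y),
        eigenvalues=lam,
        classification=classify(lam),
        residual=res,
    )


def refine_root(y0: np.ndarray, params: ModelParams, I_ext: float) -> np.ndarray | None:
    """Polish a starting guess to a root; None if it fails to converge."""
    sol = optimize.root(
        rhs_array, np.asarray(y0, float),
        args=(params, I_ext),
        method="hybr", tol=1e-13,
    )
    if not sol.success:
        return None
    if np.linalg.norm(rhs_array(sol.x, params, I_ext)) > RESIDUAL_TOL:
        return None
    return sol.x


def find_equilibria(
    params: ModelParams,
    I_ext: float,
    search_box=DEFAULT_BOX,
    n_starts: int = 4096,
    seed: int = 0,
) -> list[Equilibrium]:
    """All equilibria in the search box, deduplicated and classified.

    Multi-start quasi-Newton from a scrambled Sobol grid over ``search_box``
    (rates restricted to r >= 0).  Converged roots are deduplicated at
    Euclidean distance 1e-6 in the rate-scaled metric, roots with negative
    rate are discarded, and each survivor is re-verified (residual < 1e-9)
    with eigenvalues attached.  Deterministic for a given seed.
    """
    lo = np.asarray(search_box[0], float)
    hi = np.asarray(search_box[1], float)
    if lo[0] < 0 or lo[2] < 0:
        raise InvalidParameterError("search box must lie in the r >= 0 half-space")
    sampler = qmc.Sobol(d=4, scramble=True, rng=np.random.default_rng(seed))
    m = max(1, math.ceil(math.log2(max(n_starts, 2))))
    starts = lo + (hi - lo) * sampler.random_base2(m)[:n_starts]

    roots: list[np.ndarray] = []
    for y0 in starts:
        x = refine_root(y0, params, I_ext)
        if x is None:
            continue
        if x[0] < -1e-8 or x[2] < -1e-8:
            continue
        if np.any(x < lo - 1.0) or np.any(x > hi + 1.0):
            continue
        key = _dedup_key(x)
        if any(np.linalg.norm(key - _dedup_key(r)) < 1e-6 for r in roots):
            continue
        roots.append(x)

    eqs = [make_equilibrium(x, params, I_ext) for x in roots]
    eqs.sort(key=lambda e: e.state.r_e)
    return eqs
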