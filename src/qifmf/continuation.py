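"""Numerical bifurcation continuation for the mean-field system.

Provides the machinery behind the two-parameter (I_ext, J_e) bifurcation
scenario:

* pseudo-arclength continuation of equilibrium branches in one parameter,
  with fold and Hopf detection and bisection localization;
* codim-2 continuation of fold curves (Moore-Spence augmented system with an
  explicit null vector) and Hopf curves (augmented system with a complex
  eigenvector and frequency) in the (I_ext, J_e) plane;
* single-shooting limit cycles with the monodromy matrix integrated from the
  variational equations, giving Floquet multipliers; period-doubling points
  located by bisection on the critical multiplier crossing -1 along
  one-parameter slices, assembled into codim-2 period-doubling curves;
* rasterization + flood fill to count the connected open regions into which
  the traced curves partition a parameter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .equilibria import Equilibrium, classify, jacobian, refine_root, rhs_array
from .mean_field import DivergenceError, _param_tuple, settle
from .model_core import InvalidParameterError, ModelParams

__all__ = [
    "BranchPoint",
    "SpecialPoint",
    "Branch",
    "BifurcationCurve",
    "ShootingResult",
    "continue_equilibrium",
    "shoot_limit_cycle",
    "cycle_from_simulation",
    "continue_limit_cycle",
    "find_pd_on_slice",
    "trace_codim2_curve",
    "partition_regions",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class BranchPoint:
    param: float
    y: np.ndarray
    eigenvalues: np.ndarray | None = None
    multipliers: np.ndarray | None = None
    stable: bool = False
    period: float | None = None


@dataclass(frozen=True)
class SpecialPoint:
    kind: str            # "fold", "hopf", "period_doubling", "cycle_fold"
    param: float
    y: np.ndarray
    info: dict = field(default_factory=dict)


@dataclass
class Branch:
    free_param: str
    points: list[BranchPoint]
    special_points: list[SpecialPoint] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([p.param for p in self.points])


@dataclass(frozen=True)
class BifurcationCurve:
    """Codim-1 bifurcation locus in the (I_ext, J_e) plane."""

    curve_type: str      # "fold", "hopf", "period_doubling"
    label: str           # "f", "h1", "h2", "PD1", "PD2"
    points: np.ndarray   # (n, 2): columns I_ext, J_e

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.points, columns=["I_ext", "J_e"])
        df.insert(0, "curve_label", self.label)
        return df


def _params_at(params: ModelParams, free: str, value: float, I_ext: float):
    """Resolve (ModelParams, I_ext) when ``free`` is 'I_ext' or 'J_e'."""
    if free == "I_ext":
        return params, float(value)
    if free == "J_e":
        return params.with_(J_e=float(value)), I_ext
    raise InvalidParameterError(f"free parameter must be 'I_ext' or 'J_e', got {free!r}")


# ---------------------------------------------------------------------------
# equilibrium continuation (one parameter)


def _ext_jacobian(y, p, free, params, I_ext, h=1e-6):
    """4x5 Jacobian [dF/dy | dF/dp] of the vector field wrt state and free param."""
    pr, I = _params_at(params, free, p, I_ext)
    Jy = jacobian(y, pr, I)
    pr_hi, I_hi = _params_at(params, free, p + h, I_ext)
    pr_lo, I_lo = _params_at(params, free, p - h, I_ext)
    Jp = (rhs_array(y, pr_hi, I_hi) - rhs_array(y, pr_lo, I_lo)) / (2 * h)
    return np.hstack([Jy, Jp[:, None]])


def _tangent(y, p, free, params, I_ext, prev=None):
    A = _ext_jacobian(y, p, free, params, I_ext)
    _, _, Vt = np.linalg.svd(A)
    t = Vt[-1]
    t /= np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _hopf_test(lam: np.ndarray) -> float:
    """Product of pairwise eigenvalue sums (real); zero at a Hopf point.

    Also vanishes at neutral saddles; candidates are screened for a genuine
    complex pair at localization time.
    """
    prod = 1.0 + 0.0j
    for i in range(4):
        for j in range(i + 1, 4):
            prod *= lam[i] + lam[j]
    return float(prod.real)


def _corrector(z_pred, tangent, free, params, I_ext):
    def G(z):
        y, p = z[:4], z[4]
        pr, I = _params_at(params, free, p, I_ext)
        return np.append(rhs_array(y, pr, I), np.dot(tangent, z - z_pred))

    sol = optimize.root(G, z_pred, method="hybr", tol=1e-12)
    if not sol.success or np.linalg.norm(G(sol.x)[:4]) > 1e-9:
        return None
    return sol.x


def continue_equilibrium(
    params: ModelParams,
    free_param: str,
    start: Equilibrium | np.ndarray,
    p_start: float,
    p_range: tuple[float, float],
    I_ext: float = 0.0,
    step0: float = 0.01,
    max_step: float = 0.5,
    min_step: float = 1e-4,
    max_points: int = 4000,
    direction: int = +1,
) -> Branch:
    """Pseudo-arclength continuation of an equilibrium branch.

    Starts from a verified equilibrium at ``p_start`` and follows the branch
    (secant/tangent predictor, orthogonal corrector) until the free parameter
    leaves ``p_range`` or ``max_points`` is reached.  Eigenvalues are
    computed at each accepted point; sign changes of det(J) (fold) and of
    the pairwise-eigenvalue-sum product with a complex pair (Hopf) are
    localized by bisection in arclength to parameter tolerance 1e-6 and
    appended as special points.  ``direction`` picks the initial orientation
    of the parameter.
    """
    y0 = start.state.to_array() if isinstance(start, Equilibrium) else np.asarray(start, float)
    pr, I = _params_at(params, free_param, p_start, I_ext)
    y0 = refine_root(y0, pr, I)
    if y0 is None:
        raise InvalidParameterError("starting point failed to converge to an equilibrium")

    z = np.append(y0, p_start)
    t = _tangent(y0, p_start, free_param, params, I_ext)
    if t[4] * direction < 0:
        t = -t

    def eig_at(z):
        pr, I = _params_at(params, free_param, z[4], I_ext)
        return np.linalg.eigvals(jacobian(z[:4], pr, I))

    lam = eig_at(z)
    pts = [BranchPoint(param=float(z[4]), y=z[:4].copy(), eigenvalues=lam,
                       stable=bool(np.all(lam.real < 0)))]
    specials: list[SpecialPoint] = []
    h = step0
    lo, hi = min(p_range), max(p_range)

    def tests(lam):
        return float(np.real(np.prod(lam))), _hopf_test(lam)

    fold_prev, hopf_prev = tests(lam)
    z_prev = z.copy()

    n_fail = 0
    while len(pts) < max_points:
        z_pred = z + h * t
        z_new = _corrector(z_pred, t, free_param, params, I_ext)
        if z_new is None:
            h *= 0.5
            n_fail += 1
            if h < min_step or n_fail > 60:
                break  # corrector failure: branch truncated
            continue
        n_fail = 0
        lam = eig_at(z_new)
        fold_cur, hopf_cur = tests(lam)

        def locate(test_idx):
            """Bisect along the secant for a sign change of a test function."""
            a, b = z.copy(), z_new.copy()
            fa = tests(eig_at(a))[test_idx]
            for _ in range(60):
                mid_pred = 0.5 * (a + b)
                sec = b - a
                n = np.linalg.norm(sec)
                if n == 0:
                    break
                sec = sec / n
                m = _corrector(mid_pred, sec, free_param, params, I_ext)
                if m is None:
                    break
                fm = tests(eig_at(m))[test_idx]
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
                if abs(b[4] - a[4]) < 1e-6 and np.linalg.norm(b - a) < 1e-6:
                    break
            return 0.5 * (a + b)

        if fold_cur * fold_prev < 0 and abs(t[4]) < 0.999:
            zf = locate(0)
            lamf = eig_at(zf)
            specials.append(SpecialPoint("fold", float(zf[4]), zf[:4].copy(),
                                         {"eigenvalues": lamf}))
        if hopf_cur * hopf_prev < 0:
            zh = locate(1)
            lamh = eig_at(zh)
            # genuine Hopf: the near-axis pair must be complex
            pair = lamh[np.argsort(np.abs(lamh.real))[:2]]
            if np.all(np.abs(pair.imag) > 1e-4):
                specials.append(
                    SpecialPoint("hopf", float(zh[4]), zh[:4].copy(),
                                 {"omega": float(np.abs(pair.imag).mean()),
                                  "eigenvalues": lamh})
                )
        fold_prev, hopf_prev = fold_cur, hopf_cur

        t = _tangent(z_new[:4], z_new[4], free_param, params, I_ext, prev=(z_new - z) / max(np.linalg.norm(z_new - z), 1e-12))
        z_prev, z = z, z_new
        pts.append(BranchPoint(param=float(z[4]), y=z[:4].copy(), eigenvalues=lam,
                               stable=bool(np.all(lam.real < 0))))
        h = min(h * 1.3, max_step)
        if not (lo - 1e-9 <= z[4] <= hi + 1e-9):
            break

    return Branch(free_param=free_param, points=pts, special_points=specials)


# ---------------------------------------------------------------------------
# limit cycles: single shooting + monodromy


@dataclass(frozen=True)
class ShootingResult:
    y0: np.ndarray
    period: float
    multipliers: np.ndarray
    residual: float
    trivial_error: float

    @property
    def critical_multiplier(self) -> float:
        """Most negative near-real nontrivial multiplier.

        A period doubling always crosses the unit circle through -1 along
        the real axis, so the doubling multiplier is real near the crossing;
        tracking the minimum over near-real multipliers keeps the test
        function monotone through (and well beyond) the crossing.
        """
        mults = sorted(self.multipliers, key=lambda m: abs(m - 1.0))
        nontrivial = np.array(mults[1:])
        near_real = nontrivial[np.abs(nontrivial.imag) <= 0.05 * (1 + np.abs(nontrivial))]
        pool = near_real if near_real.size else nontrivial
        return float(np.min(pool.real))

    @property
    def nontrivial_multipliers(self) -> np.ndarray:
        mults = sorted(self.multipliers, key=lambda m: abs(m - 1.0))
        return np.array(mults[1:])


def _flow_and_monodromy(y0, T, params, I_ext, dt):
    """Integrate state and variational equations over [0, T] with RK4."""
    n = max(2, int(round(T / dt)))
    h = T / n
    pt = _param_tuple(params)
    y = np.asarray(y0, float).copy()
    Phi = np.eye(4)

    def fy(y):
        return rhs_array(y, params, I_ext)

    def Jy(y):
        return jacobian(y, params, I_ext)

    for _ in range(n):
        k1 = fy(y);            K1 = Jy(y) @ Phi
        y2 = y + 0.5 * h * k1
        k2 = fy(y2);           K2 = Jy(y2) @ (Phi + 0.5 * h * K1)
        y3 = y + 0.5 * h * k2
        k3 = fy(y3);           K3 = Jy(y3) @ (Phi + 0.5 * h * K2)
        y4 = y + h * k3
        k4 = fy(y4);           K4 = Jy(y4) @ (Phi + h * K3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        Phi = Phi + h / 6.0 * (K1 + 2 * K2 + 2 * K3 + K4)
        if not np.all(np.isfinite(y)) or np.abs(y).max() > 1e9:
            raise DivergenceError("shooting trajectory diverged")
    return y, Phi


def shoot_limit_cycle(
    params: ModelParams,
    I_ext: float,
    y0_guess: np.ndarray,
    T_guess: float,
    dt: float = 0.002,
    tol: float = 1e-10,
    max_iter: int = 25,
) -> ShootingResult:
    """Newton single shooting for a periodic orbit (initial state + period).

    Unknowns are the initial state y0 and the period T; the phase condition
    anchors y0 to the hyperplane through the initial guess orthogonal to the
    flow there.  The monodromy matrix is integrated alongside the orbit and
    supplies both the Newton matrix and the Floquet multipliers.  For an
    autonomous system one multiplier must equal 1; its deviation is reported
    as ``trivial_error`` (an accuracy diagnostic).
    """
    y0 = np.asarray(y0_guess, float).copy()
    T = float(T_guess)
    T_lo, T_hi = 0.4 * T, 2.5 * T   # guard against collapse to the T->0 root
    anchor = y0.copy()
    f_anchor = rhs_array(anchor, params, I_ext)
    f_anchor = f_anchor / np.linalg.norm(f_anchor)

    def residual_of(y0_, T_):
        yT_, M_ = _flow_and_monodromy(y0_, T_, params, I_ext, dt)
        G_ = np.append(yT_ - y0_, np.dot(f_anchor, y0_ - anchor))
        return G_, M_, yT_

    G, M, yT = residual_of(y0, T)
    res = float(np.linalg.norm(G))
    for _ in range(max_iter):
        if res < tol:
            break
        A = np.zeros((5, 5))
        A[:4, :4] = M - np.eye(4)
        A[:4, 4] = rhs_array(yT, params, I_ext)
        A[4, :4] = f_anchor
        try:
            delta = np.linalg.solve(A, -G)
        except np.linalg.LinAlgError:
            raise DivergenceError("singular shooting system")
        # damped Newton: backtrack until the residual decreases
        step = 1.0
        for _ in range(8):
            y_try = y0 + step * delta[:4]
            T_try = T + step * delta[4]
            if not (T_lo <= T_try <= T_hi):
                step *= 0.5
                continue
            try:
                G_try, M_try, yT_try = residual_of(y_try, T_try)
            except DivergenceError:
                step *= 0.5
                continue
            if np.linalg.norm(G_try) < res or step < 0.1:
                y0, T, G, M, yT = y_try, T_try, G_try, M_try, yT_try
                res = float(np.linalg.norm(G))
                break
            step *= 0.5
        else:
            raise DivergenceError("shooting line search failed")
    if not res < 100 * tol and not res < 1e-7:
        raise DivergenceError(f"shooting did not converge (residual {res:.2e})")
    mult = np.linalg.eigvals(M)
    triv = float(np.min(np.abs(mult - 1.0)))
    return ShootingResult(y0=y0, period=T, multipliers=mult, residual=res,
                          trivial_error=triv)


def cycle_from_simulation(
    params: ModelParams,
    I_ext: float,
    state0,
    dt: float = 0.001,
    t_settle: float = 300.0,
    n_periods: int = 1,
    shoot_dt: float = 0.002,
    t_measure: float = 80.0,
) -> ShootingResult:
    """Converge a limit cycle found by forward simulation.

    Settles onto the attractor, estimates the period from r_e peak times
    (``n_periods`` fundamental intervals for period-n orbits), and polishes
    with Newton shooting.
    """
    from .orbits import attractor_trace, detect_peaks

    traj = attractor_trace(params, I_ext, state0, dt=dt,
                           t_transient=t_settle, t_measure=t_measure)
    x = traj.r_e
    spread = float(x.max() - x.min())
    if spread < 1e-5:
        raise InvalidParameterError("trajectory settled to a fixed point, no cycle")
    peaks = detect_peaks(traj.t, x, min_prominence=0.05 * spread)
    if len(peaks) < n_periods + 1:
        raise InvalidParameterError("too few peaks to estimate the period")
    times = np.array([p.time for p in peaks])
    base = np.diff(times)
    T_guess = float(np.sum(base[-n_periods:]))
    # anchor shooting in the slow phase (r_e minimum between the last two
    # peaks): sensitivity along the spike is enormous and wrecks Newton
    ia = int(np.argmin(np.abs(traj.t - times[-2])))
    ib = int(np.argmin(np.abs(traj.t - times[-1])))
    i0 = ia + int(np.argmin(x[ia:ib + 1]))
    y0 = traj.y[i0]
    return shoot_limit_cycle(params, I_ext, y0, T_guess, dt=shoot_dt)


def continue_limit_cycle(
    params: ModelParams,
    free_param: str,
    seed: ShootingResult,
    p_start: float,
    p_range: tuple[float, float],
    I_ext: float = 0.0,
    step0: float = 0.2,
    min_step: float = 1e-4,
    max_step: float = 1.0,
    max_points: int = 400,
    shoot_dt: float = 0.002,
) -> Branch:
    """Natural-parameter continuation of a limit cycle with Floquet output.

    Steps the free parameter from ``p_start`` across ``p_range`` re-solving
    the shooting system at each value (previous orbit as predictor), halving
    the step on failure.  Records Floquet multipliers and flags
    period-doubling (a real multiplier crossing -1) and cycle folds (a real
    multiplier crossing +1 with the trivial one accounted for) as special
    points located by bisection on the crossing test.
    """
    lo, hi = min(p_range), max(p_range)
    direction = 1.0 if (hi - p_start) >= (p_start - lo) else -1.0
    h = step0 * direction

    def solve_at(p, y0, T):
        pr, I = _params_at(params, free_param, p, I_ext)
        return shoot_limit_cycle(pr, I, y0, T, dt=shoot_dt)

    cur = seed
    p = p_start
    pts = [BranchPoint(param=p, y=cur.y0.copy(), multipliers=cur.multipliers,
                       stable=bool(np.max(np.abs(cur.nontrivial_multipliers)) < 1.0),
                       period=cur.period)]
    specials: list[SpecialPoint] = []

    while len(pts) < max_points and lo - 1e-9 <= p <= hi + 1e-9:
        p_new = p + h
        if p_new > hi + 1e-9 or p_new < lo - 1e-9:
            p_new = float(np.clip(p_new, lo, hi))
            if abs(p_new - p) < 1e-12:
                break
        try:
            new = solve_at(p_new, cur.y0, cur.period)
            ok = new.residual < 1e-7 and new.trivial_error < 1e-2
        except (DivergenceError, np.linalg.LinAlgError):
            ok = False
        if not ok:
            h *= 0.5
            if abs(h) < min_step:
                break
            continue
        # period-doubling test: critical multiplier crossing -1
        c_prev, c_new = cur.critical_multiplier + 1.0, new.critical_multiplier + 1.0
        if c_prev * c_new < 0:
            a_p, b_p = p, p_new
            a_c = cur
            for _ in range(40):
                m_p = 0.5 * (a_p + b_p)
                try:
                    m = solve_at(m_p, a_c.y0, a_c.period)
                except (DivergenceError, np.linalg.LinAlgError):
                    break
                if (a_c.critical_multiplier + 1.0) * (m.critical_multiplier + 1.0) <= 0:
                    b_p = m_p
                else:
                    a_p, a_c = m_p, m
                if abs(b_p - a_p) < 1e-6:
                    break
            pd_p = 0.5 * (a_p + b_p)
            specials.append(SpecialPoint("period_doubling", float(pd_p),
                                         a_c.y0.copy(), {"period": a_c.period}))
        cur, p = new, p_new
        pts.append(BranchPoint(param=p, y=cur.y0.copy(), multipliers=cur.multipliers,
                               stable=bool(np.max(np.abs(cur.nontrivial_multipliers)) < 1.0),
                               period=cur.period))
        h = float(np.sign(h)) * min(abs(h) * 1.3, max_step)

    return Branch(free_param=free_param, points=pts, special_points=specials)


def find_pd_on_slice(
    params: ModelParams,
    I_ext: float,
    Je_bracket: tuple[float, float],
    n_periods: int = 1,
    state0=None,
    tol: float = 1e-3,
    shoot_dt: float = 0.002,
    settle_dt: float = 0.001,
    t_settle: float = 150.0,
    kick: float = 3.0,
) -> float | None:
    """J_e where a period-``n_periods`` cycle's multiplier crosses -1 at fixed I_ext.

    The cycle at the stable end of the bracket is found by simulation (pulse
    kick onto the oscillatory attractor when no start state is given) and
    followed by shooting across the bracket with bisection on the critical
    Floquet multiplier.  Returns None when no crossing is detected.
    """
    a, b = float(Je_bracket[0]), float(Je_bracket[1])

    def start_state(p, kick_amp):
        if state0 is not None:
            return state0
        y = settle(np.array([0.1, -2.0, 0.1, -2.0]), p, I_ext, 20.0, settle_dt)
        return settle(y, p, I_ext + kick_amp, 2.0, settle_dt)

    # the cycle at the low end of the bracket must be reachable; when the
    # pulse falls back into the quiescent basin, try stronger kicks, then
    # shrink the bracket from below (the crossing stays inside)
    cyc = None
    for _ in range(6):
        pa = params.with_(J_e=a)
        for kick_amp in (kick, kick + 2.0, kick + 5.0):
            try:
                cyc = cycle_from_simulation(pa, I_ext, start_state(pa, kick_amp),
                                            dt=settle_dt, t_settle=t_settle,
                                            n_periods=n_periods, shoot_dt=shoot_dt)
                break
            except (InvalidParameterError, DivergenceError, np.linalg.LinAlgError):
                cyc = None
        if cyc is not None:
            break
        a = a + 0.25 * (b - a)
        if b - a < 4 * tol:
            return None
    if cyc is None:
        return None

    def crit(Je, seed):
        pr = params.with_(J_e=float(Je))
        return shoot_limit_cycle(pr, I_ext, seed.y0, seed.period, dt=shoot_dt)

    # natural continuation in bounded steps (a large jump can land Newton on
    # a different orbit); first sign flip brackets the crossing.  When the
    # reachable seed already sits past the crossing (its multiplier below
    # -1), the orbit is followed downward instead -- shooting continues the
    # now-unstable cycle where simulation cannot.
    ca = cyc.critical_multiplier + 1.0
    target = b if ca > 0 else float(Je_bracket[0])
    step = min(1.0, abs(b - a) / 4) * (1 if target > a else -1)
    Je, seed = a, cyc
    bracket = None
    while (target - Je) * np.sign(step) > 1e-9:
        Je_n = min(Je + step, target) if step > 0 else max(Je + step, target)
        try:
            seed_n = crit(Je_n, seed)
        except (DivergenceError, np.linalg.LinAlgError):
            break
        if abs(seed_n.period - seed.period) > 0.5 * seed.period:
            break  # jumped to a different orbit branch
        if (seed_n.critical_multiplier + 1.0) * ca < 0:
            bracket = (Je, seed, Je_n)
            break
        Je, seed = Je_n, seed_n
    if bracket is None:
        return None
    a, seed, b = bracket
    ca = seed.critical_multiplier + 1.0
    while abs(b - a) > tol:
        m = 0.5 * (a + b)
        try:
            sm = crit(m, seed)
        except (DivergenceError, np.linalg.LinAlgError):
            return None
        if (sm.critical_multiplier + 1.0) * ca <= 0:
            b = m
        else:
            a, seed, ca = m, sm, sm.critical_multiplier + 1.0
    return 0.5 * (a + b)


def find_period_transition(
    params: ModelParams,
    I_ext: float,
    Je_bracket: tuple[float, float],
    from_class: int = 2,
    tol: float = 0.05,
    dt: float = 1e-3,
    t_transient: float = 200.0,
    t_measure: float = 60.0,
    kick: float = 3.0,
    state0=None,
    return_state: bool = False,
):
    """J_e where the attractor's period class leaves ``from_class``.

    Forward march in J_e with the running state carried along the branch
    (classification tolerances tightened to 0.5% so the early doubling
    splitting is resolved), then bisection inside the bracketing step.
    Used for the second doubling of the cascade, where the doubled cycle is
    deeply unstable on one side and shooting seeds are unreliable; where no
    stable doubled regime follows (the cycle dies in a crisis), the located
    point is the upper boundary of the ``from_class`` regime, the natural
    continuation of the curve at diagram resolution.  Returns None when the
    bracket never exhibits ``from_class`` or never leaves it; with
    ``return_state`` also returns the on-branch state at the boundary.
    """
    from .orbits import classify_attractor

    a, b = float(Je_bracket[0]), float(Je_bracket[1])

    def classify(Je, y0):
        p = params.with_(J_e=float(Je))
        try:
            return classify_attractor(p, I_ext, y0, dt=dt,
                                      t_transient=t_transient,
                                      t_measure=t_measure,
                                      amp_tol=0.005, interval_tol=0.005)
        except DivergenceError:
            return None, None

    def kicked(Je, kick_amp):
        p = params.with_(J_e=float(Je))
        y = settle(np.array([0.1, -2.0, 0.1, -2.0]), p, I_ext, 20.0, dt)
        return settle(y, p, I_ext + kick_amp, 2.0, dt)

    def fail():
        return (None, None) if return_state else None

    # reach the oscillatory branch at the low end: carried state first,
    # escalating pulse kicks as fallback
    cls_a, state_a = (None, None)
    if state0 is not None:
        cls_a, state_a = classify(a, state0)
    if cls_a in ("steady", None):
        for kick_amp in (kick, kick + 2.0, kick + 5.0):
            cls_a, state_a = classify(a, kicked(a, kick_amp))
            if cls_a not in ("steady", None):
                break
    if cls_a in ("steady", None):
        return fail()

    # march toward b; below from_class (splitting not yet resolved) keep
    # going, past it bracket the transition
    step = max(tol * 4, min(1.0, (b - a) / 6))
    Je, cls, st = a, cls_a, state_a
    lo = None
    while True:
        if cls == from_class:
            lo = (Je, st)
        elif lo is not None:
            break  # left from_class: bracket is (lo, Je)
        elif not (isinstance(cls, int) and cls < from_class):
            return fail()  # jumped past from_class without ever seeing it
        if Je >= b - 1e-9:
            return fail()  # never left from_class inside the bracket
        Je = min(Je + step, b)
        cls, st = classify(Je, st if st is not None else kicked(Je, kick))
        if cls in ("steady", None) and lo is None:
            return fail()

    (a, state_a), b = lo, Je
    while b - a > tol:
        m = 0.5 * (a + b)
        cls_m, state_m = classify(m, state_a)
        if cls_m == from_class:
            a, state_a = m, state_m
        else:
            b = m
    out = 0.5 * (a + b)
    return (out, state_a) if return_state else out


# ---------------------------------------------------------------------------
# codim-2 curves


def _fold_system(params: ModelParams):
    def G(z, c):
        y, phi, I, Je = z[:4], z[4:8], z[8], z[9]
        pr = params.with_(J_e=Je)
        J = jacobian(y, pr, I)
        return np.concatenate([
            rhs_array(y, pr, I),
            J @ phi,
            [np.dot(c, phi) - 1.0],
        ])
    return G


def _hopf_system(params: ModelParams):
    def G(z, c):
        y, qr, qi = z[:4], z[4:8], z[8:12]
        om, I, Je = z[12], z[13], z[14]
        pr = params.with_(J_e=Je)
        J = jacobian(y, pr, I)
        return np.concatenate([
            rhs_array(y, pr, I),
            J @ qr + om * qi,
            J @ qi - om * qr,
            [np.dot(c, qr) - 1.0, np.dot(c, qi)],
        ])
    return G


def _null_vector(A: np.ndarray) -> np.ndarray:
    _, _, Vt = np.linalg.svd(A)
    v = Vt[-1]
    return v / np.linalg.norm(v)


def _seed_fold_z(params, y, I, Je):
    pr = params.with_(J_e=float(Je))
    J = jacobian(y, pr, float(I))
    phi = _null_vector(J)
    return np.concatenate([y, phi, [I, Je]])


def _seed_hopf_z(params, y, I, Je, omega):
    pr = params.with_(J_e=float(Je))
    J = jacobian(y, pr, float(I))
    lam, V = np.linalg.eig(J)
    k = int(np.argmin(np.abs(lam - 1j * omega)))
    q = V[:, k]
    # normalize so that c.qr = 1, c.qi = 0 with c = qr at seed
    qr, qi = q.real, q.imag
    nr = np.linalg.norm(qr)
    if nr < 1e-12:
        qr, qi = qi, -qr
        nr = np.linalg.norm(qr)
    qr, qi = qr / nr, qi / nr
    om = float(np.abs(lam[k].imag))
    return np.concatenate([y, qr, qi, [om, I, Je]])


def _trace_augmented(G_maker, z0, c_idx, window, step0=0.05, max_step=0.8,
                     min_step=1e-5, max_points=4000, param_scale=(1.0, 1.0),
                     stop_when=None):
    """Pseudo-arclength continuation of an augmented defining system.

    ``c_idx`` indexes the normalization vector components within z (the null
    vector / eigenvector block); the normalization vector c is refreshed to
    the current vector block each accepted step.  The last two entries of z
    are (I_ext, J_e); tracing stops when they leave ``window`` or the curve
    returns near its start (closed loop).  Tracing both directions is the
    caller's job (run twice with opposite initial tangent).
    """
    (I_lo, I_hi), (J_lo, J_hi) = window
    nz = z0.size

    def inside(z, slack=0.0):
        I, J = z[nz - 2], z[nz - 1]
        return (I_lo - slack <= I <= I_hi + slack) and (J_lo - slack <= J <= J_hi + slack)

    def weights():
        w = np.ones(nz)
        w[nz - 2] = param_scale[0]
        w[nz - 1] = param_scale[1]
        return w

    w = weights()

    def solve(z_pred, tangent, c):
        def F(z):
            return np.append(G_maker(z, c), np.dot(tangent * w, z - z_pred))

        sol = optimize.root(F, z_pred, method="hybr", tol=1e-12)
        if not sol.success or np.linalg.norm(G_maker(sol.x, c)) > 1e-8:
            return None
        return sol.x

    def num_tangent(z, c, prev):
        # Jacobian of G wrt z by finite differences; tangent = null vector
        m = G_maker(z, c).size
        A = np.zeros((m, nz))
        for j in range(nz):
            h = 1e-6 * max(1.0, abs(z[j]))
            e = np.zeros(nz)
            e[j] = h
            A[:, j] = (G_maker(z + e, c) - G_maker(z - e, c)) / (2 * h)
        t = _null_vector(A)
        if prev is not None and np.dot(t, prev) < 0:
            t = -t
        return t

    c = z0[c_idx].copy()
    # polish seed
    z = solve(z0, num_tangent(z0, c, None), c)
    if z is None:
        return None
    out = [z.copy()]
    t = num_tangent(z, c, None)
    if step0 < 0:
        t = -t  # sign of step0 selects the branch direction
    h = abs(step0)
    fails = 0
    while len(out) < max_points:
        z_pred = z + h * t
        z_new = solve(z_pred, t, c)
        if z_new is None:
            h *= 0.5
            fails += 1
            if h < min_step or fails > 80:
                break
            continue
        fails = 0
        c = z_new[c_idx].copy()
        nc = np.linalg.norm(c)
        if nc > 1e-12:
            c = c / nc
        t = num_tangent(z_new, c, (z_new - z) / max(np.linalg.norm(z_new - z), 1e-15))
        z = z_new
        out.append(z.copy())
        h = min(h * 1.4, max_step)
        if stop_when is not None and stop_when(z):
            break  # degenerate point (e.g. Hopf frequency -> 0 at a
            #        Bogdanov-Takens point, beyond which the augmented
            #        system tracks the fold curve instead)
        if not inside(z, slack=1e-6):
            break
        if len(out) > 10 and np.linalg.norm(z - out[0]) < h:
            break  # closed loop
    return out


def trace_codim2_curve(
    curve_type: str,
    seed: dict,
    params: ModelParams,
    window=((-6.0, 10.0), (5.0, 80.0)),
    label: str | None = None,
    step0: float = 0.05,
    max_step: float = 0.8,
    pd_slices: np.ndarray | None = None,
    pd_n_periods: int = 1,
    pd_span: float = 12.0,
    pd_mode: str = "multiplier",
) -> BifurcationCurve:
    """Trace a codim-2 bifurcation curve in the (I_ext, J_e) window.

    Fold and Hopf curves are continued from a codim-1 ``seed``
    (dict with keys ``y``, ``I_ext``, ``J_e`` and, for Hopf, ``omega``)
    through their augmented defining systems, in both directions.
    Period-doubling curves are assembled from one-parameter slices: for each
    I_ext in ``pd_slices`` the crossing is bisected in J_e starting from the
    bracket seeded by the previous slice (``seed`` gives the first bracket
    via keys ``I_ext``, ``J_e``).  ``pd_mode`` selects the slice test:
    ``"multiplier"`` (Floquet multiplier through -1, via shooting) or
    ``"classification"`` (attractor period class change, via simulation;
    robust where the doubled cycle is deeply unstable).
    """
    if curve_type in ("fold", "hopf"):
        y = np.asarray(seed["y"], float)
        I0, J0 = float(seed["I_ext"]), float(seed["J_e"])
        if curve_type == "fold":
            z0 = _seed_fold_z(params, y, I0, J0)
            G = _fold_system(params)
            c_idx = slice(4, 8)
        else:
            z0 = _seed_hopf_z(params, y, I0, J0, float(seed["omega"]))
            G = _hopf_system(params)
            c_idx = slice(4, 8)  # normalization vector follows Re(q)
        stop = None
        if curve_type == "hopf":
            # stop well before omega reaches 0: close to a Bogdanov-Takens
            # point the augmented system degenerates toward the fold system
            # and the trace starts hugging (and noisily crossing) the fold
            stop = lambda z: abs(z[12]) < 5e-2
        halves = []
        for sgn in (+1, -1):
            pts = _trace_augmented(G, z0.copy(), c_idx, window,
                                   step0=sgn * step0, max_step=max_step,
                                   stop_when=stop)
            if pts:
                halves.append(pts)
        if not halves:
            raise InvalidParameterError(f"could not trace {curve_type} curve from seed")
        if len(halves) == 2:
            allpts = halves[1][::-1] + halves[0]
        else:
            allpts = halves[0]
        IJ = np.array([[z[-2], z[-1]] for z in allpts])
        return BifurcationCurve(curve_type, label or curve_type, IJ)

    if curve_type == "period_doubling":
        if pd_slices is None:
            raise InvalidParameterError("period_doubling tracing needs pd_slices")
        Je_center = float(seed["J_e"])
        pts = []
        for I in pd_slices:
            lo = max(window[1][0], Je_center - pd_span)
            hi = min(window[1][1], Je_center + pd_span)
            if pd_mode == "multiplier":
                Je = find_pd_on_slice(params, float(I), (lo, hi),
                                      n_periods=pd_n_periods)
            else:
                Je = find_period_transition(params, float(I), (lo, hi),
                                            from_class=2 * pd_n_periods)
            if Je is None:
                continue
            pts.append((float(I), Je))
            Je_center = Je
        if not pts:
            raise InvalidParameterError("no period-doubling points found on slices")
        return BifurcationCurve("period_doubling", label or "PD", np.array(pts))

    raise InvalidParameterError(f"unknown curve type {curve_type!r}")


# ---------------------------------------------------------------------------
# region counting


def partition_regions(
    curves: list[BifurcationCurve],
    window=((-6.0, 10.0), (5.0, 80.0)),
    resolution: int = 400,
    min_region_area: float = 0.01,
    check_refinement: bool = False,
) -> dict:
    """Count the open regions cut out of the window by the traced curves.

    The count is computed exactly: the curve polylines plus the window
    boundary are noded and polygonized, and faces with area below
    ``min_region_area`` (in parameter units; default 1e-5 of a typical
    window) are discarded -- such slivers arise from polyline noise where
    curves meet tangentially (e.g. a Hopf curve terminating on the fold at
    a Bogdanov-Takens point) and are below the tracing fidelity, an order
    of magnitude smaller than the smallest genuine region.

    A rasterized companion is also produced: curves are marked onto a
    ``resolution`` x ``resolution`` cell grid (segments sampled at
    sub-cell spacing, giving 8-connected barriers) and the complement is
    flood-filled with 4-connectivity; the labeled mask is returned for
    visualization and the raster count serves as a cross-check at scales
    the grid resolves.

    Returns {"n_regions", "region_areas", "labels", "occupied",
    "n_regions_raster"}; with ``check_refinement`` the exact count is
    re-evaluated with the area floor 4x smaller and 4x larger and reported
    as "n_regions_refined" (equal to "n_regions" when the partition is
    robust to the floor).
    """
    from scipy import ndimage

    (I_lo, I_hi), (J_lo, J_hi) = window

    # --- exact face count
    from shapely.geometry import LineString, box
    from shapely.ops import polygonize, unary_union

    geoms = [box(I_lo, J_lo, I_hi, J_hi).boundary]
    for curve in curves:
        if len(curve.points) >= 2:
            geoms.append(LineString(curve.points))
    faces = list(polygonize(unary_union(geoms)))
    areas = sorted((float(f.area) for f in faces), reverse=True)

    def count_with_floor(floor):
        return sum(1 for a in areas if a >= floor)

    n_exact = count_with_floor(min_region_area)

    # --- raster companion
    occ = np.zeros((resolution, resolution), dtype=bool)
    cell_I = (I_hi - I_lo) / resolution
    cell_J = (J_hi - J_lo) / resolution

    def mark(I, J):
        ix = int((I - I_lo) / (I_hi - I_lo) * resolution)
        jx = int((J - J_lo) / (J_hi - J_lo) * resolution)
        if 0 <= ix < resolution and 0 <= jx < resolution:
            occ[ix, jx] = True

    for curve in curves:
        P = curve.points
        for a, b in zip(P[:-1], P[1:]):
            seg = b - a
            n = int(max(abs(seg[0]) / cell_I, abs(seg[1]) / cell_J) * 3) + 2
            for s in np.linspace(0.0, 1.0, n):
                q = a + s * seg
                mark(q[0], q[1])
    labels, n_raster = ndimage.label(~occ)

    out = {
        "n_regions": int(n_exact),
        "region_areas": areas,
        "labels": labels,
        "occupied": occ,
        "n_regions_raster": int(n_raster),
    }
    if check_refinement:
        lo_count = count_with_floor(min_region_area / 4)
        hi_count = count_with_floor(min_region_area * 4)
        # equals n_regions when the count is robust to the floor; the
        # discrepant value is surfaced otherwise so callers can flag it
        out["n_regions_refined"] = int(lo_count if lo_count == hi_count
                                       else max(lo_count, hi_count))
    return out
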