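"""Branch continuation, shooting/Floquet machinery, and region counting."""

import numpy as np
import pytest

from qifmf import continuation as ct
from qifmf import equilibria as eq
from qifmf import mean_field as mf
from qifmf import orbits


@pytest.fixture(scope="module")
def je_branch(params):
    """Equilibrium branch at I_ext = -3 swept in J_e (folds + Hopf)."""
    start = eq.find_equilibria(params.with_(J_e=15.0), -3.0,
                               n_starts=256, seed=1)[0]
    return ct.continue_equilibrium(params, "J_e", start, 15.0, (5.0, 80.0),
                                   I_ext=-3.0)


@pytest.fixture(scope="module")
def p1_cycle(params):
    """Converged period-1 cycle at (I_ext, J_e) = (-3, 50)."""
    p = params.with_(J_e=50.0)
    y = mf.settle(np.array([0.1, -2.0, 0.1, -2.0]), p, -3.0, 20.0, 0.001)
    y = mf.settle(y, p, 0.0, 2.0, 0.001)
    return ct.cycle_from_simulation(p, -3.0, y, shoot_dt=1e-3)


class TestEquilibriumContinuation:
    def test_branch_covers_range_with_folds_and_hopf(self, je_branch):
        kinds = [s.kind for s in je_branch.special_points]
        assert kinds.count("fold") == 2
        assert kinds.count("hopf") >= 1
        folds = sorted(s.param for s in je_branch.special_points
                       if s.kind == "fold")
        # bistable window edges: low-J fold then high-J fold
        assert 15 < folds[0] < 30
        assert 50 < folds[1] < 80

    def test_branch_points_are_equilibria(self, je_branch, params):
        for pt in je_branch.points[:: max(1, len(je_branch.points) // 25)]:
            res = np.linalg.norm(
                eq.rhs_array(pt.y, params.with_(J_e=pt.param), -3.0))
            assert res < 1e-9

    def test_special_points_match_brute_force_scan(self, je_branch, params):
        """Fold/Hopf parameters agree with stability/count changes found by
        independent multistart scans on a fine grid."""
        folds = sorted(s.param for s in je_branch.special_points
                       if s.kind == "fold")
        lo_fold = folds[0]
        grid = np.linspace(lo_fold - 0.5, lo_fold + 0.5, 11)
        counts = [len(eq.find_equilibria(params.with_(J_e=float(J)), -3.0,
                                         n_starts=192, seed=6)) for J in grid]
        # count changes 1 -> 3 inside one grid cell around the detected fold
        change = [i for i in range(10) if counts[i] != counts[i + 1]]
        assert len(change) == 1
        a, b = grid[change[0]], grid[change[0] + 1]
        assert a - 1e-3 <= lo_fold <= b + 1e-3

    def test_hopf_agrees_with_stability_scan(self, je_branch, params):
        hopf = [s for s in je_branch.special_points if s.kind == "hopf"][0]
        for dJ, expect_stable in ((-0.2, True), (0.2, False)):
            p = params.with_(J_e=hopf.param + dJ)
            eqs = eq.find_equilibria(p, -3.0, n_starts=256, seed=8)
            high = max(eqs, key=lambda e: e.state.r_e)
            assert high.is_stable == expect_stable

    def test_reversibility(self, je_branch, params):
        """Continuing forward then backward returns to the start point."""
        start_y = je_branch.points[0].y
        fwd = ct.continue_equilibrium(params, "J_e", start_y, 15.0,
                                      (15.0, 25.0), I_ext=-3.0)
        end = fwd.points[-1]
        back = ct.continue_equilibrium(params, "J_e", end.y, end.param,
                                       (15.0, end.param), I_ext=-3.0,
                                       direction=-1)
        # the backward branch crosses the start parameter; interpolate the
        # state there, polish, and compare with the original start point
        ps = back.params
        assert ps.min() <= 15.0 <= ps.max()
        k = int(np.argmin(np.abs(ps - 15.0)))
        y15 = eq.refine_root(back.points[k].y, params.with_(J_e=15.0), -3.0)
        assert y15 is not None
        assert np.linalg.norm(y15 - start_y) < 1e-5


class TestShooting:
    def test_trivial_multiplier_unity(self, p1_cycle):
        assert p1_cycle.residual < 1e-8
        assert p1_cycle.trivial_error < 1e-3

    def test_stable_cycle_multipliers_inside_unit_circle(self, p1_cycle):
        assert np.max(np.abs(p1_cycle.nontrivial_multipliers)) < 1.0

    def test_period_matches_simulation(self, p1_cycle, params):
        p = params.with_(J_e=50.0)
        traj = orbits.attractor_trace(p, -3.0, p1_cycle.y0, dt=0.001,
                                      t_transient=50.0, t_measure=30.0)
        peaks = orbits.detect_peaks(traj.t, traj.r_e,
                                    0.05 * np.ptp(traj.r_e))
        sim_T = np.mean(np.diff([pk.time for pk in peaks]))
        assert p1_cycle.period == pytest.approx(sim_T, rel=1e-3)

    def test_perturbed_start_returns_to_cycle(self, p1_cycle, params):
        """Stability cross-check by time stepping: a small perturbation
        relaxes back onto the orbit."""
        p = params.with_(J_e=50.0)
        y = p1_cycle.y0 * 1.02 + 0.01
        end = mf.settle(y, p, -3.0, 60.0, 0.001)
        traj = orbits.attractor_trace(p, -3.0, end, dt=0.001,
                                      t_transient=10.0, t_measure=10.0)
        # the relaxed trajectory passes within a tight distance of y0
        d = np.min(np.linalg.norm(traj.y - p1_cycle.y0, axis=1))
        assert d < 0.05 * np.linalg.norm(p1_cycle.y0)


class TestPeriodDoublingDetection:
    def test_multiplier_crossing_located(self, params):
        pd1 = ct.find_pd_on_slice(params, -3.0, (50.0, 60.0), shoot_dt=1e-3)
        assert pd1 is not None
        # just below: critical multiplier above -1; just above: below -1
        for dJ, sign in ((-0.3, 1.0), (0.3, -1.0)):
            p = params.with_(J_e=pd1 + dJ)
            y = mf.settle(np.array([0.1, -2.0, 0.1, -2.0]), p, -3.0, 20.0, 0.001)
            y = mf.settle(y, p, 0.0, 2.0, 0.001)
            cyc = ct.cycle_from_simulation(p, -3.0, y,
                                           n_periods=1 if dJ < 0 else 2,
                                           shoot_dt=1e-3)
            if dJ < 0:
                assert cyc.critical_multiplier > -1.0
        # attractor side-check: period class doubles across the crossing
        cls_lo, _ = orbits.classify_attractor(
            params.with_(J_e=pd1 - 0.5), -3.0, y, t_transient=300.0,
            t_measure=100.0, amp_tol=0.005, interval_tol=0.005)
        cls_hi, _ = orbits.classify_attractor(
            params.with_(J_e=pd1 + 0.5), -3.0, y, t_transient=300.0,
            t_measure=100.0, amp_tol=0.005, interval_tol=0.005)
        assert cls_lo == 1
        assert cls_hi == 2


class TestLimitCycleContinuation:
    def test_branch_records_doubling(self, p1_cycle, params):
        """Continuing the period-1 cycle in J_e crosses the doubling: the
        critical multiplier passes -1 and the special point agrees with the
        independent slice bisection."""
        br = ct.continue_limit_cycle(params, "J_e", p1_cycle, 50.0,
                                     (50.0, 57.0), I_ext=-3.0, step0=0.5,
                                     shoot_dt=1e-3)
        pds = [s for s in br.special_points if s.kind == "period_doubling"]
        assert len(pds) == 1
        pd_slice = ct.find_pd_on_slice(params, -3.0, (52.0, 58.0),
                                       shoot_dt=1e-3)
        assert abs(pds[0].param - pd_slice) < 0.05
        # stability flag flips across the doubling
        stables = [p.stable for p in br.points]
        assert stables[0] is True and stables[-1] is False


class TestCodim2Defining:
    def test_fold_and_hopf_conditions_reverified(self, params, je_branch):
        """Points on traced codim-2 curves satisfy their defining eigenvalue
        conditions."""
        folds = [s for s in je_branch.special_points if s.kind == "fold"]
        hopfs = [s for s in je_branch.special_points if s.kind == "hopf"]
        fold_curve = ct.trace_codim2_curve(
            "fold", {"y": folds[0].y, "I_ext": -3.0, "J_e": folds[0].param},
            params, window=((-4.0, -2.0), (15.0, 30.0)), label="f")
        for I, J in fold_curve.points[::5]:
            x = eq.refine_root(folds[0].y, params.with_(J_e=J), I)
            # curve points carry only (I, J); re-solve the equilibrium there
            lam = np.linalg.eigvals(
                eq.jacobian(x, params.with_(J_e=J), I)) if x is not None else None
            assert lam is not None
            assert np.min(np.abs(lam)) < 1e-4
        hopf_curve = ct.trace_codim2_curve(
            "hopf", {"y": hopfs[0].y, "I_ext": -3.0, "J_e": hopfs[0].param,
                     "omega": hopfs[0].info["omega"]},
            params, window=((-4.0, -2.0), (35.0, 50.0)), label="h")
        for I, J in hopf_curve.points[::5]:
            x = eq.refine_root(hopfs[0].y, params.with_(J_e=J), I)
            assert x is not None
            lam = np.linalg.eigvals(eq.jacobian(x, params.with_(J_e=J), I))
            near = lam[np.argsort(np.abs(lam.real))[:2]]
            assert np.all(np.abs(near.real) < 1e-4)
            assert np.all(np.abs(near.imag) > 0.1)


class TestPartitionRegions:
    def test_empty_curve_list_single_region(self):
        out = ct.partition_regions([], resolution=100)
        assert out["n_regions"] == 1

    def test_single_line_two_regions(self):
        line = ct.BifurcationCurve("fold", "f",
                                   np.array([[-6.0, 40.0], [10.0, 45.0]]))
        out = ct.partition_regions([line], resolution=150,
                                   check_refinement=True)
        assert out["n_regions"] == 2
        assert out["n_regions_refined"] == 2

    def test_cross_four_regions(self):
        v = ct.BifurcationCurve("hopf", "h",
                                np.array([[2.0, 5.0], [2.0, 80.0]]))
        h = ct.BifurcationCurve("fold", "f",
                                np.array([[-6.0, 40.0], [10.0, 40.0]]))
        out = ct.partition_regions([v, h], resolution=150)
        assert out["n_regions"] == 4

    def test_interior_endpoint_does_not_separate(self):
        stub = ct.BifurcationCurve("fold", "f",
                                   np.array([[-6.0, 40.0], [0.0, 40.0]]))
        out = ct.partition_regions([stub], resolution=150)
        assert out["n_regions"] == 1
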