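"""Peak detection, period classification, ISI sweeps, Lyapunov exponent."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qifmf import mean_field as mf
from qifmf import orbits
from qifmf.model_core import ModelParams, StimulusProtocol
from qifmf.protocols import fixture_signal


class TestDetectPeaks:
    def test_sinusoid_peaks(self):
        t, x, truth = fixture_signal("sinusoid", period=2 * math.pi, n_cycles=10)
        peaks = orbits.detect_peaks(t, x, min_prominence=0.5)
        assert len(peaks) == 10
        amps = np.array([p.amplitude for p in peaks])
        np.testing.assert_allclose(amps, 3.0, atol=1e-4)
        spacing = np.diff([p.time for p in peaks])
        np.testing.assert_allclose(spacing, 2 * math.pi, atol=1e-3)

    def test_constant_trace_no_peaks(self):
        t = np.linspace(0, 10, 1000)
        assert orbits.detect_peaks(t, np.ones_like(t), 0.01) == []

    def test_alternating_amplitudes_preserved(self):
        t, x, _ = fixture_signal("alternating_peaks")
        peaks = orbits.detect_peaks(t, x, min_prominence=0.1)
        amps = np.array([p.amplitude for p in peaks])
        assert len(amps) >= 8
        # consecutive peaks alternate high/low
        assert np.all(np.sign(np.diff(amps)[::2]) == np.sign(amps[1] - amps[0]))


class TestClassifyPeriod:
    @pytest.mark.parametrize(
        "kind, expected",
        [("sinusoid", 1), ("alternating_peaks", 2), ("period4_peaks", 4)],
    )
    def test_fixture_classes(self, kind, expected):
        t, x, truth = fixture_signal(kind)
        peaks = orbits.detect_peaks(t, x, min_prominence=0.05)
        assert orbits.classify_period(peaks) == expected == truth["period_class"]

    def test_too_few_peaks_raise(self):
        peaks = [orbits.Peak(float(i), 1.0) for i in range(5)]
        with pytest.raises(orbits.InsufficientDataError):
            orbits.classify_period(peaks)

    def test_random_amplitudes_chaotic(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(0.5 + rng.uniform(0, 1, 40))
        peaks = [orbits.Peak(t, a) for t, a in
                 zip(times, 1 + rng.uniform(0, 1, 40))]
        assert orbits.classify_period(peaks) == "chaotic"

    @settings(max_examples=40, deadline=None)
    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
        n_class=st.sampled_from([1, 2, 4]),
    )
    def test_invariance_under_shift_and_scale(self, shift, scale, n_class):
        kind = {1: "sinusoid", 2: "alternating_peaks", 4: "period4_peaks"}[n_class]
        t, x, _ = fixture_signal(kind)
        peaks = orbits.detect_peaks(t, x, min_prominence=0.05)
        moved = [orbits.Peak(p.time + shift, p.amplitude * scale) for p in peaks]
        assert orbits.classify_period(moved) == n_class


class TestMeanFieldAttractors:
    def test_strong_drive_period1(self, params):
        # steady strong drive at default coupling: regular synchronization
        cls, _ = orbits.classify_attractor(params, 8.0,
                                           np.array([0.1, -2.0, 0.1, -2.0]),
                                           t_transient=100.0, t_measure=60.0)
        assert cls == 1

    def test_poincare_points_match_period(self, params):
        p = params.with_(J_e=58.0)
        y = mf.settle(np.array([0.1, -2.0, 0.1, -2.0]), p, -3.0, 20.0, 0.001)
        y = mf.settle(y, p, 0.0, 2.0, 0.001)
        traj = orbits.attractor_trace(p, -3.0, y, dt=0.001,
                                      t_transient=300.0, t_measure=80.0)
        peaks = orbits.detect_peaks(traj.t, traj.r_e,
                                    0.05 * np.ptp(traj.r_e))
        n = orbits.classify_period(peaks)
        assert n == 2
        pts = orbits.poincare_points(traj)
        # n distinct section points for a period-n orbit
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        clusters = []
        for p_ in pts:
            for c in clusters:
                if np.linalg.norm(p_ - c) < 0.05 * np.linalg.norm(c):
                    break
            else:
                clusters.append(p_)
        assert len(clusters) == n

    def test_section_level_insensitivity(self, params):
        p = params.with_(J_e=58.0)
        y = mf.settle(np.array([0.1, -2.0, 0.1, -2.0]), p, -3.0, 20.0, 0.001)
        y = mf.settle(y, p, 0.0, 2.0, 0.001)
        traj = orbits.attractor_trace(p, -3.0, y, dt=0.001,
                                      t_transient=300.0, t_measure=80.0)
        base = float(np.mean(traj.r_e))
        counts = {len(orbits.poincare_points(traj, level=base * s))
                  for s in (0.9, 1.0, 1.1)}
        assert len(counts) == 1


class TestISISweep:
    def test_single_point_period1_region(self, params):
        sweep = orbits.isi_bifurcation_sweep(
            params, -3.0, np.array([50.0]), t_transient=150.0, t_measure=60.0)
        assert len(sweep.intervals) == 1
        iv = sweep.intervals[0]
        assert iv.size >= 8
        # one interval cluster: all intervals nearly equal
        assert np.ptp(iv) < 0.02 * np.mean(iv)

    def test_continue_and_fixed_agree_on_unique_attractor(self, params):
        grid = np.array([10.0, 12.0, 14.0])  # strong-drive tongue, one attractor
        a = orbits.isi_bifurcation_sweep(params, 8.0, grid, init_mode="continue",
                                         t_transient=100.0, t_measure=50.0)
        b = orbits.isi_bifurcation_sweep(params, 8.0, grid, init_mode="fixed",
                                         state0=np.array([0.1, -2.0, 0.1, -2.0]),
                                         t_transient=100.0, t_measure=50.0)
        for iva, ivb in zip(a.intervals, b.intervals):
            assert abs(np.mean(iva) - np.mean(ivb)) < 0.01 * np.mean(iva)

    def test_frame_long_format(self, params):
        sweep = orbits.isi_bifurcation_sweep(
            params, -3.0, np.array([50.0]), t_transient=120.0, t_measure=50.0)
        df = sweep.to_frame()
        assert set(df.columns) == {"J_e", "interval"}
        assert (df["interval"] > 0).all()


class TestLyapunov:
    def test_negative_at_stable_focus(self, params):
        # start in the basin of the high-rate focus at (5, 30); the exponent
        # approaches the leading eigenvalue real part (~ -0.024)
        from qifmf import equilibria as eq

        p = params.with_(J_e=30.0)
        focus = max(eq.find_equilibria(p, 5.0, n_starts=512, seed=2),
                    key=lambda e: e.state.r_e)
        assert focus.classification == "stable focus"
        lam = orbits.lyapunov_max(p, 5.0, t_total=400.0, seed=1,
                                  state0=focus.state.to_array(), t_settle=20.0)
        assert lam < -0.01

    def test_near_zero_on_limit_cycle(self, params):
        # neutral direction along the orbit dominates
        lam = orbits.lyapunov_max(params, 8.0, t_total=2000.0, seed=1)
        assert abs(lam) < 0.01

    def test_deterministic_given_seed(self, params):
        a = orbits.lyapunov_max(params, 8.0, t_total=200.0, seed=3)
        b = orbits.lyapunov_max(params, 8.0, t_total=200.0, seed=3)
        assert a == b
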