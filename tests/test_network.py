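"""Spiking-network simulation: gates, stepping, rates, voltage density."""

import math

import numpy as np
import pytest

from qifmf import network as net
from qifmf.model_core import InvalidParameterError, ModelParams, StimulusProtocol
from qifmf.protocols import fixture_signal


class TestSynapticActivation:
    @pytest.mark.parametrize(
        "V, expected",
        [
            (np.zeros(10), 0.0),
            (np.array([60.0, 40.0]), 0.5),
            (np.array([51.0, 52.0, 53.0, 49.0]), 0.75),
        ],
    )
    def test_counts(self, V, expected):
        assert net.synaptic_activation(V, 50.0) == expected

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            net.synaptic_activation(np.array([]), 50.0)


class TestStepNetwork:
    def test_uncoupled_rest_state(self):
        # eta + I_ext = -1: stable rest at V = -1 (root of V^2 - 1)
        p = ModelParams(J_e=0.0, J_i=0.0)
        state = net.NetworkState(
            V_e=np.array([0.0]), V_i=np.array([0.0]),
            eta_e=np.array([-1.0]), eta_i=np.array([-1.0]))
        for _ in range(20000):
            state, se, si = net.step_network(state, 1e-3, 0.0, p)
        assert state.V_e[0] == pytest.approx(-1.0, abs=1e-3)

    def test_single_neuron_isi_matches_closed_form(self):
        # dV/dt = V^2 + 1 between the cutoffs: ISI = 2*arctan(V_peak)/sqrt(1)
        p = ModelParams(J_e=0.0, J_i=0.0)
        expected = net.single_neuron_isi(1.0, p.V_peak, p.V_reset)
        assert expected == pytest.approx(2 * math.atan(p.V_peak), rel=1e-12)
        # closed form at an explicit finite cutoff, for reference
        assert net.single_neuron_isi(1.0, 100.0, -100.0) == \
            pytest.approx(3.1216, abs=1e-4)
        state = net.NetworkState(
            V_e=np.array([p.V_reset]), V_i=np.array([p.V_reset]),
            eta_e=np.array([1.0]), eta_i=np.array([1.0]))
        dt = 1e-3
        spike_steps = []
        for k in range(15000):
            state, se, _ = net.step_network(state, dt, 0.0, p)
            if len(se):
                spike_steps.append(k)
        isis = np.diff(spike_steps) * dt
        assert len(isis) >= 2
        assert np.mean(isis) == pytest.approx(expected, rel=0.01)

    def test_tiny_step_leaves_state_unchanged(self, params):
        state = net.init_state(params, 50, 50, seed=0)
        new, _, _ = net.step_network(state, 1e-9, 0.0, params)
        np.testing.assert_allclose(new.V_e, state.V_e, atol=1e-6)

    def test_blowup_names_neuron_and_time(self, params):
        state = net.NetworkState(
            V_e=np.array([1e200]), V_i=np.array([0.0]),
            eta_e=np.array([0.0]), eta_i=np.array([0.0]))
        with pytest.raises(net.SimulationBlowupError, match="population e"):
            net.step_network(state, 1.0, 0.0, params)


class TestRunNetwork:
    def test_degenerate_quiet_network_never_spikes(self):
        # all eta = -1 (point heterogeneity), V(0) = -1: everyone at rest
        p = ModelParams(J_e=0.0, J_i=0.0, eta_bar=-1.0)
        state = net.init_state(p, 100, 100, het_mode="degenerate", V0=-1.0)
        out = net.run_network(p, 100, 100, StimulusProtocol.constant(0.0, 5.0),
                              dt=1e-3, state=state)
        assert len(out["raster"]) == 0
        assert out["rate_e"].rate.max() == 0.0

    def test_gate_traces_bounded(self, params):
        out = net.run_network(params, 200, 200,
                              StimulusProtocol.constant(0.0, 5.0), dt=1e-3, seed=1)
        assert out["S_e"].min() >= 0.0 and out["S_e"].max() <= 1.0
        assert out["S_i"].min() >= 0.0 and out["S_i"].max() <= 1.0

    def test_step_drive_switches_to_oscillation(self, params):
        proto = StimulusProtocol.from_steps([0.0, 8.0], [4.0], 12.0)
        out = net.run_network(params, 500, 500, proto, dt=1e-3, seed=2)
        r = out["rate_e"]
        pre = r.rate[(r.t > 1.0) & (r.t < 4.0)]
        post = r.rate[r.t > 6.0]
        cv_pre = np.std(pre) / max(np.mean(pre), 1e-9)
        cv_post = np.std(post) / max(np.mean(post), 1e-9)
        assert cv_post > 5 * cv_pre

    def test_finite_size_convergence_to_meanfield(self, params,
                                                  quiescent_state):
        """The quiescent rate error against the infinite-size limit shrinks
        as the network grows."""
        errs = []
        for N in (500, 2000, 8000):
            out = net.run_network(params, N, N,
                                  StimulusProtocol.constant(0.0, 15.0),
                                  dt=1e-3, seed=1)
            r = out["rate_e"].mean_rate(t_min=5.0)
            errs.append(abs(r - quiescent_state.state.r_e))
        assert errs[2] < errs[0]
        assert errs[2] < 0.15 * quiescent_state.state.r_e

    def test_quiescent_rate_brackets_meanfield_prediction(self, params,
                                                          quiescent_state):
        out = net.run_network(params, 1000, 1000,
                              StimulusProtocol.constant(0.0, 15.0), dt=1e-3,
                              seed=3)
        r_net = out["rate_e"].mean_rate(t_min=5.0)
        r_mf = quiescent_state.state.r_e
        assert 0.5 * r_mf < r_net < 2.0 * r_mf


class TestPopulationRate:
    def test_single_bin_rate(self):
        raster = net.SpikeRaster(
            times=np.full(100, 0.5), population=np.full(100, "e"),
            neuron=np.arange(100))
        trace = net.population_rate(raster, N=100, bin_width=1.0, smooth_bins=1,
                                    duration=1.0)
        assert trace.rate[0] == pytest.approx(1.0)

    def test_empty_raster_zero_trace(self):
        raster = net.SpikeRaster(times=np.empty(0), population=np.empty(0, "U1"),
                                 neuron=np.empty(0, int))
        trace = net.population_rate(raster, N=10, bin_width=0.05, duration=2.0)
        assert np.all(trace.rate == 0.0)

    def test_rate_integral_conserves_spike_count(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 10, 500))
        raster = net.SpikeRaster(times=times, population=np.full(500, "e"),
                                 neuron=rng.integers(0, 50, 500))
        trace = net.population_rate(raster, N=50, bin_width=0.05, smooth_bins=1,
                                    duration=10.0)
        integral = np.sum(trace.rate) * 0.05 * 50
        assert integral == pytest.approx(500, rel=1e-12)

    def test_poisson_rate_recovered(self):
        fx = fixture_signal("poisson_raster", seed=9, lam=0.2, N=100, T=100.0)
        raster = net.SpikeRaster(times=fx["times"],
                                 population=np.full(fx["times"].size, "e"),
                                 neuron=fx["neuron"])
        trace = net.population_rate(raster, N=100, bin_width=0.5, smooth_bins=1,
                                    duration=100.0)
        est = trace.mean_rate()
        se = math.sqrt(0.2 / (100 * 100.0))  # Poisson counting error
        assert abs(est - 0.2) < 3 * se


class TestVoltageDistribution:
    def test_exact_lorentzian_sample_small_distance(self):
        rng = np.random.default_rng(21)
        r, v = 1.5, -2.0
        V = v + math.pi * r * np.tan(math.pi * (rng.uniform(size=10**4) - 0.5))
        stat = net.voltage_distribution_check(V, r, v, trim=40.0)
        assert stat < 0.03

    def test_point_mass_distance_half(self):
        V = np.full(1000, -2.0)
        stat = net.voltage_distribution_check(V, 1.0, -2.0, trim=10.0)
        assert stat == pytest.approx(0.5, abs=1e-3)

    def test_invalid_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            net.voltage_distribution_check(np.zeros(10), 0.0, 0.0, 1.0)
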