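import numpy as np
import pytest

from avnet import (
    KernelSet,
    ModelParams,
    Network,
    StimulusEvent,
    build_kernels,
    detect_rt,
    measure_crossmodal_latency,
    measure_input_latency,
    simulate,
)
from avnet.kernels import sigmoid
from avnet.stimuli import make_rt_sequence


from conftest import zero_kernels


class TestSingleUnitOracle:
    """With every coupling zeroed, each unit is a first-order system whose
    step response has the closed form y(t) = F(u) * (1 - exp(-t / tau))."""

    def test_step_response_matches_closed_form(self):
        p = ModelParams(dt_ms=0.1)
        net = Network(p, kernels=zero_kernels(p.n_units), batch=1)
        u = 35.0
        # hold the filtered external input constant at u from t = 0
        net.state.e_a[:] = u
        net._E_a[:] = u
        n_steps = int(100.0 / p.dt_ms)
        ts, ys = [], []
        for k in range(n_steps):
            net.step()
            ts.append(net.state.t_ms)
            ys.append(net.state.y["a"][90, 0])
        ts, ys = np.array(ts), np.array(ys)
        f_u = float(sigmoid(u, p.theta, p.slope))
        expected = f_u * (1 - np.exp(-ts / p.tau_unit))
        # error measured against the response scale F(u); pointwise relative
        # error additionally holds once the transient has developed (t >= tau)
        assert np.max(np.abs(ys - expected)) / f_u < 0.01
        late = ts >= p.tau_unit
        assert np.all(np.abs(ys[late] - expected[late]) / expected[late] < 0.01)
        # activity at t = tau is 63.2% of the asymptote, up to explicit
        # Euler's O(dt/tau) bias (~1.1% at dt = 0.1 ms); the bias halves with
        # the step, confirming first-order convergence
        k_tau = int(round(p.tau_unit / p.dt_ms)) - 1
        target = (1 - np.exp(-1.0)) * f_u
        err_01 = abs(ys[k_tau] - target)
        assert err_01 / target < 0.015
        p2 = ModelParams(dt_ms=0.05)
        net2 = Network(p2, kernels=zero_kernels(p2.n_units), batch=1)
        net2.state.e_a[:] = u
        net2._E_a[:] = u
        for _ in range(int(round(p2.tau_unit / p2.dt_ms))):
            net2.step()
        err_005 = abs(net2.state.y["a"][90, 0] - target)
        assert err_005 < 0.6 * err_01

    def test_quiescent_fixed_point(self):
        p = ModelParams(dt_ms=0.1)
        net = Network(p, kernels=zero_kernels(p.n_units), batch=1)
        res = net.run([[]], 50.0)
        f0 = float(sigmoid(0.0, p.theta, p.slope))
        assert f0 == pytest.approx(5.5e-4, rel=0.01)
        assert res.pm_max.max() <= f0 * 1.001


class TestNetworkBasics:
    def test_quiescence_and_bounds_without_stimulation(self, params):
        res = simulate(make_rt_sequence(params, 2, seed=0), params,
                       trace_areas=("a", "v", "m", "pm"), extra_window_ms=100.0)
        for area, tr in res.traces.items():
            assert tr.min() >= 0.0
            assert tr.max() <= 1.0

    def test_initial_state_is_quiet(self, params):
        net = Network(params, batch=2)
        for y in net.state.y.values():
            assert np.all(y < 1e-3)

    def test_single_auditory_stimulus_forms_central_bubble(self, params):
        ev = StimulusEvent("a", 0.0, 50.0, 60.0, params.i0_a, 0)
        net = Network(params, batch=1)
        res = net.run([[ev]], 160.0, snapshot_times_ms=[110.0])
        y = res.snapshots[110.0]["a"][:, 0]
        assert int(y.argmax()) == 90
        assert y.max() > 0.5

    def test_same_seed_same_trajectories(self, params):
        seq = make_rt_sequence(params, 3, seed=42)
        r1 = simulate(seq, params, trace_areas=("pm",), extra_window_ms=400.0)
        r2 = simulate(seq, params, trace_areas=("pm",), extra_window_ms=400.0)
        assert np.array_equal(r1.traces["pm"], r2.traces["pm"])

    def test_negative_onsets_rejected(self, params):
        net = Network(params, batch=1)
        ev = StimulusEvent("a", 0.0, 0.0, 60.0, 1.0, 0)
        object.__setattr__(ev, "onset_ms", -1.0)
        with pytest.raises(ValueError):
            net.run([[ev]], 100.0)

    def test_dt_must_divide_delays(self, params):
        with pytest.raises(ValueError, match="multiple"):
            Network(params.replace(dt_ms=0.3), batch=1)

    def test_trajectory_dump_is_long_format(self, params):
        ev = StimulusEvent("a", 0.0, 10.0, 60.0, params.i0_a, 0)
        net = Network(params, batch=1)
        res = net.run([[ev]], 50.0, trace_areas=("a", "pm"), trace_stride=50)
        frame = res.trace_frame()
        assert set(frame.columns) == {"time_ms", "area", "unit_index", "activity"}
        assert set(frame.area) == {"a", "pm"}


class TestEmergentTiming:
    def test_auditory_precedes_visual_at_equal_strength(self, params):
        """Input-area threshold crossings order as tau_a < tau_v when the
        stimuli are matched in strength and spatial spread (the asymmetric
        spreads otherwise confound the comparison through lateral dynamics)."""
        matched = params.replace(sigma_v=params.sigma_a, i0_v=params.i0_a)
        times = {}
        for m in ("a", "v"):
            ev = StimulusEvent(m, 0.0, 0.0, 200.0, matched.i0_a, 0)
            net = Network(matched, batch=1)
            res = net.run([[ev]], 200.0, trace_areas=(m,), trace_stride=1)
            peak = res.traces[m][:, :, 0].max(axis=1)
            times[m] = res.trace_times_ms[int(np.argmax(peak >= 0.5))]
        assert times["a"] < times["v"]

    def test_crossmodal_influence_is_subthreshold_for_detection(self, params):
        """A unisensory stimulus modulates the other input area but must not
        drive a premotor response through the cross-modal route alone."""
        for m in ("a", "v"):
            ev = StimulusEvent(m, 0.0, 50.0, 60.0,
                               params.i0_for(m) * (1 + params.jitter_rel), 0)
            net = Network(params, batch=1)
            other = "v" if m == "a" else "a"
            res = net.run([[ev]], 400.0, trace_areas=(other,), trace_stride=5)
            halo = res.traces[other].max()
            assert halo > 1e-3          # the influence exists...
            assert halo < 0.7           # ...but stays below a full response
            # and the stimulated modality's own premotor response is the only one
            assert res.pm_max.max() > params.rt_threshold

    def test_integration_step_convergence(self, params):
        """Halving the integration step moves detected RTs by well under 1 ms."""
        rts = {}
        for dt in (params.dt_ms, params.dt_ms / 2):
            p = params.replace(dt_ms=dt)
            ev = StimulusEvent("a", 0.0, 100.0, 60.0, p.i0_a, 0)
            net = Network(p, batch=1)
            res = net.run([[ev]], 600.0)
            rts[dt] = detect_rt(res.pm_max[:, 0], dt, 100.0, p.rt_threshold)
        vals = list(rts.values())
        assert abs(vals[0] - vals[1]) < 1.0


class TestLatencyMeasures:
    def test_input_latencies_are_physiological(self, params):
        assert 10.0 < measure_input_latency(params, "a") <= 30.0
        assert 15.0 < measure_input_latency(params, "v") <= 50.0

    def test_crossmodal_latency_finite_and_fast(self, params):
        assert measure_crossmodal_latency(params, "a") <= 40.0
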