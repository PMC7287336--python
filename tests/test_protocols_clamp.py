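"""Protocol templates and the piecewise-analytic clamp engine."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gatecal.channels import channel_steady_state
from gatecal.clamp import propagate_segment, run_protocol, steady_state
from gatecal.protocols import (
    SWEEP,
    ProtocolError,
    ProtocolSegment,
    ProtocolTemplate,
    activation_iv,
    availability,
    builtin_templates,
    load_protocol,
    protocol_from_dict,
    pulse_train,
    recovery,
    save_protocol,
)


class TestTemplates:
    def test_library_contents(self):
        lib = builtin_templates()
        assert set(lib) == {
            "activation_iv", "availability", "recovery", "deactivation", "pulse_train"
        }

    def test_recovery_sweeps_and_recorded_pulses(self):
        p = recovery(intervals=[1.0, 2.0, 5.0, 10.0])
        assert p.n_sweeps == 4
        for iv in p.sweep_values:
            segs = p.realize(iv)
            recorded = [s for s in segs if s.record]
            assert len(recorded) == 2  # P1 and P2

    def test_activation_sweep_count(self):
        p = activation_iv(test_voltages=np.arange(-60, 61, 10))
        assert p.n_sweeps == 13

    def test_pulse_train_period(self):
        p = pulse_train(n_pulses=100, pulse_ms=100.0, rate_hz=1.0)
        # one period = pulse + gap = 1000 ms
        segs = p.realize(p.sweep_values[0])
        pulse, gap = segs[1], segs[2]
        assert pulse.duration + gap.duration == pytest.approx(1000.0)
        assert sum(1 for s in segs if s.voltage == -30.0) == 100

    def test_exactly_one_sweep_marker_enforced(self):
        with pytest.raises(ProtocolError):
            ProtocolTemplate(
                "bad",
                [ProtocolSegment(SWEEP, SWEEP, record=True)],
                "v",
                [1.0],
            )
        with pytest.raises(ProtocolError):
            ProtocolTemplate(
                "bad",
                [ProtocolSegment(-80.0, 10.0, record=True)],
                "v",
                [1.0],
            )

    def test_recorded_segment_required(self):
        with pytest.raises(ProtocolError):
            ProtocolTemplate("bad", [ProtocolSegment(SWEEP, 10.0)], "v", [1.0])

    def test_round_trip(self, tmp_path):
        p = availability(conditioning_voltages=[-100.0, -80.0, -60.0])
        path = tmp_path / "proto.yaml"
        save_protocol(p, path)
        q = load_protocol(path)
        assert q.name == p.name
        np.testing.assert_allclose(q.sweep_values, p.sweep_values)
        assert [s.voltage for s in q.segments] == [s.voltage for s in p.segments]

    def test_named_template_config(self):
        p = protocol_from_dict({"template": "activation_iv", "holding": -90.0})
        assert p.segments[0].voltage == -90.0
        with pytest.raises(ProtocolError):
            protocol_from_dict({"template": "no_such_template"})


class TestPropagation:
    def test_long_segment_relaxes_to_steady_state(self, single_gate, single_gate_truth):
        params = single_gate.params_dict(single_gate_truth)
        end, _ = propagate_segment(single_gate, params, {"a": 0.0}, -20.0, 5000.0)
        ss = channel_steady_state(single_gate, -20.0, params)
        assert end["a"] == pytest.approx(float(ss["a"][0]), abs=1e-12)

    def test_one_tau_relaxation_fraction(self, plain_gate_channel):
        # gamma_inf = 1 requires beta = 0; after t = tau, gamma = 1 - 1/e
        params = {"g.lam1": 1.0, "g.lam2": 0.0, "g.lam3": 0.0, "g.lam4": 0.0}
        end, _ = propagate_segment(plain_gate_channel, params, {"g": 0.0}, 0.0, 1.0)
        assert end["g"] == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_chaining_is_associative(self, single_gate, single_gate_truth, rng):
        params = single_gate.params_dict(single_gate_truth)
        g0 = {"a": 0.3}
        one, _ = propagate_segment(single_gate, params, g0, -30.0, 17.0)
        d1 = 17.0 * rng.uniform(0.2, 0.8)
        mid, _ = propagate_segment(single_gate, params, g0, -30.0, d1)
        two, _ = propagate_segment(single_gate, params, mid, -30.0, 17.0 - d1)
        assert two["a"] == pytest.approx(one["a"], abs=1e-14)

    def test_monotone_within_segment(self, single_gate, single_gate_truth):
        params = single_gate.params_dict(single_gate_truth)
        t = np.linspace(0, 50, 400)
        _, traj = propagate_segment(single_gate, params, {"a": 0.0}, -10.0, 50.0, t)
        diffs = np.diff(traj["a"])
        assert np.all(diffs >= -1e-15)

    def test_matches_ode_oracle(self, two_gate, two_gate_truth):
        """Analytic propagation agrees with adaptive Runge-Kutta on the
        gating ODE to |dgamma| < 1e-8 over a multi-segment protocol."""
        params = two_gate.params_dict(two_gate_truth)
        segments = [(-100.0, 20.0), (-20.0, 25.0), (-100.0, 10.0), (-20.0, 25.0)]
        state = steady_state(two_gate, params, segments[0][0])

        for V, dur in segments:
            end, _ = propagate_segment(two_gate, params, state, V, dur)
            kin = channel_steady_state(two_gate, V, params)

            def rhs(t, y):
                return [
                    (float(kin[g.name][0]) - y[i]) / float(kin[g.name][1])
                    for i, g in enumerate(two_gate.gates)
                ]

            y0 = [state[g.name] for g in two_gate.gates]
            sol = solve_ivp(rhs, (0, dur), y0, method="RK45", rtol=1e-11, atol=1e-12)
            for i, g in enumerate(two_gate.gates):
                assert abs(end[g.name] - sol.y[i, -1]) < 1e-8
            state = end


class TestRunProtocol:
    def test_flat_trace_at_steady_state(self, single_gate, single_gate_truth):
        p = ProtocolTemplate(
            "const",
            [ProtocolSegment(SWEEP, 50.0, record=True)],
            "v",
            [-20.0],
            sample_interval=0.5,
        )
        traces = run_protocol(single_gate, single_gate_truth, p)
        assert len(traces) == 1
        np.testing.assert_allclose(
            traces[0].current, traces[0].current[0], rtol=1e-12
        )

    def test_one_trace_per_sweep_value(self, single_gate, single_gate_truth):
        p = activation_iv(test_voltages=np.arange(-60, 41, 20), sample_interval=0.5)
        traces = run_protocol(single_gate, single_gate_truth, p)
        assert len(traces) == 6
        assert [t.sweep_value for t in traces] == list(p.sweep_values)

    def test_gate_trajectories_bounded(self, two_gate, two_gate_truth):
        p = availability(
            conditioning_voltages=[-120.0, -80.0, -40.0],
            conditioning_ms=200.0,
            sample_interval=0.1,
        )
        for tr in run_protocol(two_gate, two_gate_truth, p):
            for g, vals in tr.gates.items():
                assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))
            assert np.all(np.diff(tr.times) > 0)

    def test_pulse_train_identical_pulses_when_fully_recovered(
        self, two_gate, two_gate_truth
    ):
        """With a long enough inter-pulse interval the channel fully recovers,
        so pulse 1 and pulse 100 produce identical currents."""
        p = pulse_train(
            n_pulses=100,
            holding=-140.0,
            pulse_voltage=-30.0,
            pulse_ms=100.0,
            rate_hz=1.0,
            record_all=True,
            sample_interval=0.5,
        )
        (trace,) = run_protocol(two_gate, two_gate_truth, p)
        first = trace.current[trace.windows[0].sl]
        last = trace.current[trace.windows[-1].sl]
        np.testing.assert_allclose(last, first, rtol=1e-9, atol=1e-12)
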