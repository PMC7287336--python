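"""Summary statistics: peaks, steady-state curves, exponential fits, recovery."""

import numpy as np
import pytest

from gatecal.channels import RateParams, build_standard_channel, eval_rates
from gatecal.clamp import Trace, RecordedWindow, run_protocol
from gatecal.protocols import activation_iv, recovery
from gatecal.summaries import (
    ExperimentDesign,
    FitError,
    SummaryCurve,
    fit_time_constant,
    peak_current,
    recovery_fraction,
    simulate_summary,
    steady_state_curve,
)
from gatecal.synthetic import SINGLE_GATE_TRUTH, single_gate_channel


def make_trace(current, sweep_value=0.0):
    current = np.asarray(current, dtype=float)
    t = np.arange(current.size, dtype=float)
    return Trace(
        times=t,
        current=current,
        gates={},
        sweep_value=sweep_value,
        windows=[RecordedWindow(0, slice(0, current.size), 0.0, 0.0)],
    )


class TestPeakCurrent:
    def test_constant_trace(self):
        assert peak_current(make_trace(np.full(20, 3.5))) == 3.5

    def test_interior_minimum_sign_preserved(self):
        y = np.concatenate([np.linspace(0, -5, 10), np.linspace(-5, -1, 10)])
        assert peak_current(make_trace(y)) == -5.0

    def test_agrees_with_exhaustive_scan(self, rng):
        for _ in range(20):
            y = rng.normal(size=50)
            expected = y[np.argmax(np.abs(y))]
            assert peak_current(make_trace(y)) == expected


class TestSteadyStateCurve:
    def test_pinned_open_gives_all_ones(self):
        # gates pinned open -> peak conductance proxy constant -> all-ones
        ch = build_standard_channel(
            {"name": "c", "reversal_potential": -85.0,
             "gates": [{"name": "a", "constant": 1.0}]}
        )
        p = activation_iv(test_voltages=np.arange(-60, 41, 20), sample_interval=1.0)
        curve = steady_state_curve(run_protocol(ch, [], p), "activation", ch)
        np.testing.assert_allclose(curve.y, 1.0)

    def test_recovers_closed_form_boltzmann(self):
        """With long steps, the activation curve equals gamma_inf(V)
        normalized, computed in closed form from the Eyring parameters."""
        ch = single_gate_channel()
        volts = np.arange(-60.0, 41.0, 10.0)
        p = activation_iv(test_voltages=volts, step_ms=400.0, sample_interval=0.5)
        curve = steady_state_curve(
            run_protocol(ch, SINGLE_GATE_TRUTH, p), "activation", ch
        )
        lam = [SINGLE_GATE_TRUTH[f"a.lam{i}"] for i in (1, 2, 3, 4)]
        gi = 1.0 / (1.0 + (lam[2] / lam[0]) * np.exp(-(lam[1] + lam[3]) * volts))
        np.testing.assert_allclose(curve.y, gi / np.max(np.abs(gi)), atol=1e-3)

    def test_normalization_idempotent(self):
        c = SummaryCurve("steady_state_activation", [0, 1, 2], [0.1, 0.5, 1.0])
        m = np.max(np.abs(c.y))
        np.testing.assert_allclose(c.y / m, c.y)

    def test_conductance_invariance(self):
        """Scaling the channel conductance by 10 leaves every normalized
        summary curve unchanged."""
        ch1 = single_gate_channel()
        ch10 = single_gate_channel()
        ch10.conductance = 10.0
        p = activation_iv(test_voltages=np.arange(-60, 41, 10), sample_interval=0.5)
        for mode in ("activation",):
            c1 = steady_state_curve(run_protocol(ch1, SINGLE_GATE_TRUTH, p), mode, ch1)
            c10 = steady_state_curve(run_protocol(ch10, SINGLE_GATE_TRUTH, p), mode, ch10)
            np.testing.assert_allclose(c10.y, c1.y, rtol=1e-12)

    def test_v_equals_e_point_excluded_with_warning(self):
        ch = single_gate_channel()  # E = -85
        p = activation_iv(test_voltages=np.array([-85.0, -20.0, 0.0]), sample_interval=0.5)
        with pytest.warns(UserWarning, match="zero driving force"):
            curve = steady_state_curve(run_protocol(ch, SINGLE_GATE_TRUTH, p), "activation", ch)
        assert curve.x.size == 2


class TestFitTimeConstant:
    def test_single_exponential_exact(self):
        t = np.arange(0, 40, 0.05)
        y = 2.0 + 3.0 * np.exp(-t / 5.0)
        taus, amps, c, _ = fit_time_constant(t, y, 1)
        assert taus[0] == pytest.approx(5.0, abs=1e-4)
        assert amps[0] == pytest.approx(3.0, rel=1e-3)
        assert c == pytest.approx(2.0, rel=1e-3)

    def test_double_exponential_within_one_percent(self):
        t = np.arange(0, 300, 0.1)
        y = 0.05 + 0.7 * np.exp(-t / 2.0) + 0.3 * np.exp(-t / 50.0)
        taus, amps, _, _ = fit_time_constant(t, y, 2)
        assert taus[0] == pytest.approx(2.0, rel=0.01)
        assert taus[1] == pytest.approx(50.0, rel=0.01)
        assert amps[0] == pytest.approx(0.7, rel=0.01)
        assert amps[1] == pytest.approx(0.3, rel=0.01)

    def test_fitted_tau_equals_inverse_rate_sum(self):
        """A single-gate channel stepped to fixed V relaxes with
        tau = 1/(alpha+beta); the fitted value matches within 0.1%."""
        ch = single_gate_channel()
        volts = np.arange(-50.0, 1.0, 10.0)
        design = ExperimentDesign(
            name="tau",
            statistic_type="time_constant",
            protocol=activation_iv(test_voltages=volts, step_ms=80.0, sample_interval=0.05),
        )
        curve = simulate_summary(ch, SINGLE_GATE_TRUTH, design)
        lam = RateParams(*[SINGLE_GATE_TRUTH[f"a.lam{i}"] for i in (1, 2, 3, 4)])
        from gatecal.channels import GateSpec

        gate = GateSpec("a")
        for V, tau_hat in zip(curve.x, curve.y):
            alpha, beta = eval_rates(gate, V, lam)
            assert tau_hat == pytest.approx(1.0 / (alpha + beta), rel=1e-3)

    def test_constant_trace_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(FitError):
            fit_time_constant(t, np.ones_like(t), 1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitError):
            fit_time_constant(np.arange(5.0), np.arange(5.0), 1)


class TestRecoveryFraction:
    def test_long_intervals_recover_fully(self, two_gate, two_gate_truth):
        p = recovery(intervals=np.array([200.0, 400.0, 800.0]), sample_interval=0.05)
        design = ExperimentDesign("rec", "recovery_fraction", p)
        curve = simulate_summary(two_gate, two_gate_truth, design)
        np.testing.assert_allclose(curve.y, 1.0, atol=1e-4)

    def test_monotone_nondecreasing_in_interval(self, two_gate, rng):
        """For a single-inactivation-gate channel, recovery fraction grows
        with the inter-pulse interval (property over sampled parameters)."""
        p = recovery(intervals=np.array([1.0, 3.0, 10.0, 30.0, 100.0]), sample_interval=0.05)
        design = ExperimentDesign("rec", "recovery_fraction", p)
        for _ in range(5):
            theta = {
                "m.lam1": rng.uniform(5, 30), "m.lam2": rng.uniform(0.05, 0.15),
                "m.lam3": rng.uniform(0.1, 1.0), "m.lam4": rng.uniform(0.02, 0.08),
                "h.lam1": rng.uniform(0.1, 1.0), "h.lam2": rng.uniform(0.03, 0.08),
                "h.lam3": rng.uniform(1e-5, 1e-4), "h.lam4": rng.uniform(0.05, 0.09),
            }
            curve = simulate_summary(two_gate, theta, design)
            assert np.all(np.diff(curve.y) >= -1e-9)

    def test_zero_p1_rejected(self):
        with pytest.raises(ValueError):
            recovery_fraction([0.0, 1.0], [0.5, 0.5], [1.0, 2.0])


class TestSummaryCurveValidation:
    def test_monotone_x_required(self):
        with pytest.raises(ValueError):
            SummaryCurve("peak_iv", [0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            SummaryCurve("nope", [0.0], [1.0])
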