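"""Channel model: Eyring rates, steady-state/tau transform, parameter counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatecal.channels import (
    ChannelConfigError,
    ChannelSpec,
    GateSpec,
    InvalidParameterError,
    PriorBox,
    RateParams,
    build_standard_channel,
    channel_current,
    channel_from_dict,
    channel_steady_state,
    channel_to_dict,
    courtemanche_ina_layout,
    default_standard_prior,
    eval_rates,
    gate_steady_state_tau,
    load_channel,
    nygren_ina_layout,
    save_channel,
    standard_ina_layout,
)


def make_gate(role="activating", **kw):
    return GateSpec(name="g", role=role, **kw)


class TestEyringRates:
    @pytest.mark.parametrize(
        "lams, V, expected",
        [
            ((2.0, 0.0, 3.0, 0.0), -80.0, (2.0, 3.0)),  # zero voltage sensitivity
            ((1.0, 0.01, 1.0, 0.01), 100.0, (np.e, 1.0 / np.e)),
        ],
    )
    def test_known_values(self, lams, V, expected):
        alpha, beta = eval_rates(make_gate(), V, RateParams(*lams))
        assert alpha == pytest.approx(expected[0], rel=1e-12)
        assert beta == pytest.approx(expected[1], rel=1e-12)

    @given(
        l1=st.floats(0, 100),
        l2=st.floats(0, 0.4),
        l3=st.floats(0, 100),
        l4=st.floats(0, 0.4),
        V=st.floats(-150, 100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rates_nonnegative(self, l1, l2, l3, l4, V):
        alpha, beta = eval_rates(make_gate(), V, RateParams(l1, l2, l3, l4))
        assert alpha >= 0 and beta >= 0
        assert np.isfinite(alpha) and np.isfinite(beta)

    def test_negative_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            RateParams(-1.0, 0.1, 1.0, 0.1)

    def test_overflow_signalled(self):
        g = make_gate()
        with pytest.raises(InvalidParameterError):
            eval_rates(g, 1e5, RateParams(1.0, 0.4, 1.0, 0.4))


class TestSteadyStateTau:
    def test_activating_equal_rates(self):
        gi, tau = gate_steady_state_tau(make_gate(), 0.0, RateParams(1, 0, 1, 0))
        assert gi == pytest.approx(0.5)
        assert tau == pytest.approx(0.5)

    def test_inactivating_branch(self):
        # gamma_inf = beta * tau for an inactivating gate
        gi, tau = gate_steady_state_tau(
            make_gate("inactivating"), 0.0, RateParams(1, 0, 3, 0)
        )
        assert gi == pytest.approx(0.75)
        assert tau == pytest.approx(0.25)

    def test_tied_gate_scales_tau_only(self):
        tied = GateSpec(name="h2", role="inactivating", tied_to="h1")
        gi, tau = gate_steady_state_tau(tied, 0.0, {}, sibling=(0.5, 0.5), scale=10.0)
        assert gi == pytest.approx(0.5)
        assert tau == pytest.approx(5.0)

    def test_degenerate_gate_raises(self):
        with pytest.raises(InvalidParameterError):
            gate_steady_state_tau(make_gate(), 0.0, RateParams(0, 0, 0, 0))

    def test_steady_state_in_unit_interval_and_tau_positive(self):
        g = make_gate()
        V = np.linspace(-120, 60, 50)
        gi, tau = gate_steady_state_tau(g, V, RateParams(0.5, 0.08, 0.01, 0.05))
        assert np.all((gi > 0) & (gi < 1))
        assert np.all(tau > 0)

    def test_steady_state_depends_only_on_ratio_and_sum(self):
        """gamma_inf is invariant to scaling (lam1, lam3) jointly and to
        shifting (lam2, lam4) at fixed sum."""
        g = make_gate()
        V = np.linspace(-100, 60, 33)
        base = RateParams(0.5, 0.08, 0.01, 0.05)
        gi0, _ = gate_steady_state_tau(g, V, base)
        scaled = RateParams(0.5 * 37.0, 0.08, 0.01 * 37.0, 0.05)
        gi1, _ = gate_steady_state_tau(g, V, scaled)
        shifted = RateParams(0.5, 0.11, 0.01, 0.02)  # sum of sensitivities kept
        gi2, _ = gate_steady_state_tau(g, V, shifted)
        np.testing.assert_allclose(gi1, gi0, rtol=1e-12)
        np.testing.assert_allclose(gi2, gi0, rtol=1e-12)


class TestChannelCurrent:
    def test_fully_open(self):
        ch = build_standard_channel(
            {"name": "c", "reversal_potential": -80.0, "gates": [{"name": "a"}]}
        )
        assert channel_current(ch, {"a": 1.0}, 0.0) == pytest.approx(80.0)

    def test_any_closed_gate_zeroes_current(self, two_gate):
        assert channel_current(two_gate, {"m": 0.0, "h": 0.7}, 0.0) == 0.0

    def test_exponent_applied(self):
        ch = ChannelSpec(
            "c", [GateSpec("a", exponent=3)], conductance=2.0, reversal_potential=0.0
        )
        assert channel_current(ch, {"a": 0.5}, 10.0) == pytest.approx(2.5)


class TestParameterCounting:
    def test_standard_ina_has_nine_parameters(self):
        ch = standard_ina_layout()
        assert ch.free_parameter_count == 9

    def test_published_structure_counts(self):
        assert nygren_ina_layout().free_parameter_count == 15
        assert courtemanche_ina_layout().free_parameter_count == 29

    def test_single_gate_four_parameters(self, plain_gate_channel):
        assert plain_gate_channel.free_parameter_count == 4

    def test_two_untied_gates_eight(self, two_gate):
        assert two_gate.free_parameter_count == 8

    @pytest.mark.parametrize("n_untied, n_tied", list(itertools.product([1, 2, 3], [0, 1, 2])))
    def test_count_matches_name_enumeration(self, n_untied, n_tied):
        """Free-parameter count = 4 * untied + tied, verified against a
        brute-force enumeration of the qualified parameter names."""
        gates = [{"name": f"u{i}"} for i in range(n_untied)]
        gates += [
            {"name": f"t{i}", "role": "inactivating", "tied_to": "u0"} for i in range(n_tied)
        ]
        ch = build_standard_channel({"name": "c", "gates": gates})
        expected_names = []
        for i in range(n_untied):
            expected_names += [f"u{i}.lam{k}" for k in (1, 2, 3, 4)]
        for i in range(n_tied):
            expected_names += [f"t{i}.scale"]
        assert sorted(ch.param_names) == sorted(expected_names)
        assert ch.free_parameter_count == 4 * n_untied + n_tied

    def test_tied_to_missing_gate_rejected(self):
        with pytest.raises(ChannelConfigError):
            build_standard_channel(
                {"name": "c", "gates": [{"name": "a", "tied_to": "nope"}]}
            )

    def test_tied_to_self_rejected(self):
        with pytest.raises(ChannelConfigError):
            GateSpec("a", tied_to="a")

    def test_gatewise_calibration_via_fixed_rate_gates(self):
        """High-dimensional channels are calibrated one gate at a time: the
        other gates carry numeric rate expressions with no free symbols and
        contribute zero free parameters."""
        from gatecal.channels import ExpressionRates

        fixed_m = GateSpec(
            "m",
            "activating",
            exponent=3,
            rates=ExpressionRates("20*exp(0.12*V)", "0.4*exp(-0.05*V)", []),
        )
        free_h = GateSpec("h", "inactivating")
        ch = ChannelSpec("Na.gatewise", [fixed_m, free_h], reversal_potential=60.0)
        assert ch.param_names == ("h.lam1", "h.lam2", "h.lam3", "h.lam4")
        assert ch.free_parameter_count == 4

    def test_constant_gate_contributes_no_parameters(self):
        ch = build_standard_channel(
            {"name": "c", "gates": [{"name": "a"}, {"name": "fca", "constant": 1.0}]}
        )
        assert ch.free_parameter_count == 4


class TestTiedGateKinetics:
    def test_tied_gate_in_channel_steady_state(self):
        ch = standard_ina_layout()
        theta = {
            "m.lam1": 1.0, "m.lam2": 0.1, "m.lam3": 1.0, "m.lam4": 0.1,
            "h1.lam1": 1.0, "h1.lam2": 0.05, "h1.lam3": 2.0, "h1.lam4": 0.05,
            "h2.scale": 7.0,
        }
        ss = channel_steady_state(ch, -20.0, theta)
        assert ss["h2"][0] == pytest.approx(ss["h1"][0])
        assert ss["h2"][1] == pytest.approx(7.0 * ss["h1"][1])


class TestPriors:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(ChannelConfigError):
            PriorBox(["a"], [1.0], [1.0])

    def test_default_standard_prior_shapes(self, single_gate):
        prior = default_standard_prior(single_gate)
        assert prior.names == single_gate.param_names
        assert prior.dim == 4
        assert np.all(prior.lower < prior.upper)

    def test_sample_and_contains(self, single_gate, rng):
        prior = default_standard_prior(single_gate)
        draws = prior.sample(rng, 100)
        assert draws.shape == (100, 4)
        assert np.all(prior.contains(draws))
        assert not prior.contains(prior.upper + 1.0)


class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "factory", [standard_ina_layout, nygren_ina_layout, courtemanche_ina_layout]
    )
    def test_dict_round_trip_preserves_structure(self, factory):
        ch = factory()
        clone = channel_from_dict(channel_to_dict(ch))
        assert clone.name == ch.name
        assert clone.param_names == ch.param_names
        assert clone.free_parameter_count == ch.free_parameter_count
        assert clone.reversal_potential == ch.reversal_potential

    def test_yaml_file_round_trip(self, tmp_path, single_gate, single_gate_truth):
        path = tmp_path / "channel.yaml"
        save_channel(single_gate, path)
        clone = load_channel(path)
        assert clone.param_names == single_gate.param_names
        V = np.linspace(-80, 40, 7)
        ss0 = channel_steady_state(single_gate, V, single_gate_truth)
        ss1 = channel_steady_state(clone, V, single_gate_truth)
        for g in ss0:
            np.testing.assert_allclose(ss1[g][0], ss0[g][0])
            np.testing.assert_allclose(ss1[g][1], ss0[g][1])

    def test_malformed_config_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("gates: [{name: a}]\n")  # missing channel name
        with pytest.raises((ChannelConfigError, KeyError)):
            load_channel(path)


class TestExpressionRates:
    def test_expression_evaluation_matches_formula(self):
        from gatecal.channels import ExpressionRates

        r = ExpressionRates("k1*exp(k2*V)", "k3/(1 + exp((V + k4)/k5))", ["k1", "k2", "k3", "k4", "k5"])
        params = {"k1": 2.0, "k2": 0.03, "k3": 1.5, "k4": 30.0, "k5": 8.0}
        a, b = r(-20.0, params)
        assert a == pytest.approx(2.0 * np.exp(0.03 * -20))
        assert b == pytest.approx(1.5 / (1 + np.exp((-20 + 30) / 8.0)))

    def test_undeclared_symbol_rejected(self):
        from gatecal.channels import ExpressionRates

        with pytest.raises(ChannelConfigError):
            ExpressionRates("k1*exp(k2*V)", "oops*V", ["k1", "k2"])
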