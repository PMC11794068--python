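"""Kernel unit and property tests: validation, ordering, DELAY1 algebra,
Euler integration, steady-state oracle, linearity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdpricing import (
    Delay1Spec,
    ModelError,
    ModelSpec,
    SimConfig,
    SimulationError,
    Term,
    VariableSpec,
    asymptotic_values,
    delay1_init,
    delay1_step,
    dependency_order,
    generate_fixture_model,
    scale_model,
    simulate,
    validate_model,
)
from conftest import FLOW, STOCK


def tiny_model(terms_a=(Term.lit(1.0),)):
    return ModelSpec(
        variables=[
            VariableSpec.constant("c", 2.0),
            VariableSpec.auxiliary("a", list(terms_a)),
            VariableSpec.stock("s", "a", 0.0),
        ]
    )


class TestTypes:
    def test_term_field_discipline(self):
        with pytest.raises(ModelError):
            Term(coefficient=1.0, kind="literal")  # missing literal_value
        with pytest.raises(ModelError):
            Term(coefficient=float("nan"), kind="literal", literal_value=1.0)
        with pytest.raises(ModelError):
            Term(coefficient=1.0, kind="ref")  # missing source
        with pytest.raises(ModelError):
            Term(coefficient=1.0, kind="delay1", source="x")  # missing delay spec

    def test_delay_spec_discipline(self):
        with pytest.raises(ModelError):
            Delay1Spec(delay_time=0.0)
        with pytest.raises(ModelError):
            Delay1Spec(delay_time=1.0, init_policy="explicit")  # missing value
        with pytest.raises(ModelError):
            Delay1Spec(delay_time=1.0, init_policy="zero", init_value=3.0)

    def test_variable_kind_discipline(self):
        with pytest.raises(ModelError):
            VariableSpec(name="x", kind="constant")  # no value
        with pytest.raises(ModelError):
            VariableSpec(name="x", kind="flow")
        with pytest.raises(ModelError):
            VariableSpec(name="x", kind="stock", inflow="a")  # no initial

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dt=0.0),
            dict(t_end=-1.0),
            dict(t_end=50.3),  # not an integer number of dt=1 steps
            dict(save_every=0),
        ],
    )
    def test_sim_config_rejects_bad_grids(self, kwargs):
        with pytest.raises(ModelError):
            SimConfig(**kwargs)


class TestValidation:
    def test_japan_model_is_valid(self, japan):
        assert validate_model(japan) == []

    def test_algebraic_cycle_is_reported(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.auxiliary("A", [Term.ref("B")]),
                VariableSpec.auxiliary("B", [Term.ref("A")]),
                VariableSpec.stock("s", "A", 0.0),
            ]
        )
        issues = validate_model(spec)
        assert len(issues) == 1
        assert "A" in issues[0] and "B" in issues[0] and "cycle" in issues[0]

    def test_unresolved_reference_is_reported(self):
        spec = tiny_model(terms_a=[Term.ref("X")])
        issues = validate_model(spec)
        assert len(issues) == 1
        assert "X" in issues[0]

    def test_duplicate_name_and_bad_inflow(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.constant("c", 1.0),
                VariableSpec.constant("c", 2.0),
                VariableSpec.stock("s", "nope", 0.0),
            ]
        )
        issues = validate_model(spec)
        assert any("duplicate" in i for i in issues)
        assert any("nope" in i for i in issues)

    def test_delay_closed_loop_is_allowed(self):
        # a delayed self-influence carries state and must not count as a cycle
        spec = ModelSpec(
            variables=[
                VariableSpec.auxiliary("a", [Term.lit(1.0), Term.delay1("a", 2.0)]),
                VariableSpec.stock("s", "a", 0.0),
            ]
        )
        assert validate_model(spec) == []
        simulate(spec, SimConfig(t_end=5))


class TestDependencyOrder:
    def test_chain_orders_upstream_first(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.auxiliary("a", [Term.ref("b")]),
                VariableSpec.auxiliary("b", [Term.ref("c")]),
                VariableSpec.auxiliary("c", [Term.lit(1.0)]),
                VariableSpec.stock("s", "a", 0.0),
            ]
        )
        assert dependency_order(spec) == ["c", "b", "a"]

    def test_japan_new_mechanism_precedes_new_action_part(self, japan):
        order = dependency_order(japan)
        assert order.index("new mechanism") < order.index("new action part")

    def test_no_auxiliaries_gives_empty_order(self):
        spec = ModelSpec(variables=[VariableSpec.constant("c", 1.0)])
        assert dependency_order(spec) == []

    def test_ties_follow_declaration_order(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.auxiliary("z", [Term.lit(1.0)]),
                VariableSpec.auxiliary("a", [Term.lit(2.0)]),
            ]
        )
        assert dependency_order(spec) == ["z", "a"]


class TestDelayPrimitives:
    @pytest.mark.parametrize(
        "policy,init_value,input0,expected",
        [("zero", None, 8.0, 0.0), ("equilibrium", None, 8.0, 8.0), ("explicit", 3.5, 8.0, 3.5)],
    )
    def test_init_policies(self, policy, init_value, input0, expected):
        d = Delay1Spec(1.0, policy, init_value)
        assert delay1_init(d, input0, dt=1.0) == expected

    def test_auto_policy_resolves_by_step_size(self):
        d = Delay1Spec(0.5, "auto")
        assert delay1_init(d, 8.0, dt=1.0) == 8.0  # shorter than the step -> equilibrium
        assert delay1_init(d, 8.0, dt=0.5) == 0.0  # otherwise zero-start

    def test_step_examples(self):
        assert delay1_step(0.0, 8.0, 5.0, 1.0) == pytest.approx(1.6, abs=0)
        assert delay1_step(8.0, 8.0, 3.7, 0.25) == 8.0  # fixed point
        assert delay1_step(0.0, 2.0, 0.5, 0.5) == 2.0  # one-step convergence at dt=T

    def test_step_rejects_non_positive_times(self):
        with pytest.raises(ModelError):
            delay1_step(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ModelError):
            delay1_step(0.0, 1.0, 1.0, -1.0)

    @given(
        out0=st.floats(-50, 50),
        target=st.floats(-50, 50),
        delay_time=st.floats(0.5, 10),
        n=st.integers(1, 60),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_geometric_convergence_closed_form(self, out0, target, delay_time, n):
        """For constant input the deviation decays exactly geometrically:
        |out_n - I| = |out_0 - I| * (1 - dt/T)^n."""
        dt = 0.25
        out = out0
        for _ in range(n):
            out = delay1_step(out, target, delay_time, dt)
        expected = target + (out0 - target) * (1 - dt / delay_time) ** n
        assert out == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("dt", [0.1, 0.5, 1.0, 1.9])
    def test_integrated_deficit_equals_input_times_delay(self, dt):
        """Sum of (I - out_n) * dt over the horizon tends to I*T for any
        dt < 2T — the reason step-halving barely moves the stock."""
        target, delay_time = 8.0, 1.0
        out, acc, t = 0.0, 0.0, 0.0
        while t < 400:
            acc += (target - out) * dt
            out = delay1_step(out, target, delay_time, dt)
            t += dt
        assert acc == pytest.approx(target * delay_time, rel=1e-9)


class TestSimulate:
    def test_zero_inputs_stay_zero(self, japan, config):
        traj = simulate(scale_model(japan, 0.0), config)
        for name, series in traj.series.items():
            assert np.all(series == 0.0), name

    def test_equilibrium_init_japan_stock_is_linear(self, japan, config):
        traj = simulate(japan, config, delay_init="equilibrium")
        assert traj.value_at(STOCK, 50.0) == pytest.approx(5321.25, abs=1e-9)
        # every auxiliary constant in time, stock exactly linear
        flow = traj.series[FLOW]
        assert np.ptp(flow) == 0.0
        expected = traj.times * flow[0]
        assert np.allclose(traj.series[STOCK], expected, atol=1e-8)

    def test_default_init_flow_converges_to_asymptote(self, japan, config):
        traj = simulate(japan, config)
        target = asymptotic_values(japan)[FLOW]
        assert abs(traj.value_at(FLOW, 50.0) - target) / target < 1e-3

    def test_non_finite_intermediate_aborts_with_diagnostic(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.constant("c", 1e308),
                VariableSpec.auxiliary("blow", [Term.ref("c", 1e308)]),
                VariableSpec.stock("s", "blow", 0.0),
            ]
        )
        with pytest.raises(SimulationError, match="blow"):
            simulate(spec, SimConfig(t_end=2))

    def test_invalid_model_is_rejected(self):
        spec = tiny_model(terms_a=[Term.ref("X")])
        with pytest.raises(ModelError):
            simulate(spec, SimConfig(t_end=2))

    def test_save_grid_includes_endpoints_and_interval(self, japan):
        traj = simulate(japan, SimConfig(t_end=50, dt=0.5, save_every=4))
        assert traj.times[0] == 0.0 and traj.times[-1] == 50.0
        assert np.allclose(np.diff(traj.times), 2.0)

    def test_time_off_grid_raises(self, japan):
        traj = simulate(japan, SimConfig(t_end=5))
        with pytest.raises(KeyError):
            traj.value_at(STOCK, 2.5)


class TestAsymptotics:
    def test_japan_values(self, japan):
        asym = asymptotic_values(japan)
        assert asym["value premium"] == pytest.approx(30.0, abs=1e-12)
        assert asym["sakigake premium"] == pytest.approx(8.0, abs=1e-12)
        assert asym["rare disease drug"] == pytest.approx(13.0, abs=1e-12)

    def test_delay_free_model_matches_single_evaluation(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.constant("c", 3.0),
                VariableSpec.auxiliary("a", [Term.lit(1.0), Term.ref("c", 2.0)]),
                VariableSpec.auxiliary("b", [Term.ref("a", 0.5)]),
                VariableSpec.stock("s", "b", 0.0),
            ]
        )
        asym = asymptotic_values(spec)
        assert asym == {"c": 3.0, "a": 7.0, "b": 3.5}

    def test_matches_long_run_simulation(self, japan):
        asym = asymptotic_values(japan)
        # 20x the largest delay time
        traj = simulate(japan, SimConfig(t_end=100))
        for name in ("value premium", "pediatrics premium", FLOW):
            assert abs(traj.value_at(name, 100.0) - asym[name]) <= 1e-6 * max(1.0, abs(asym[name]))

    def test_stock_dependence_has_no_asymptote(self):
        spec = ModelSpec(
            variables=[
                VariableSpec.auxiliary("a", [Term.lit(1.0), Term.ref("s", 0.1)]),
                VariableSpec.stock("s", "a", 0.0),
            ]
        )
        with pytest.raises(ModelError, match="stock"):
            asymptotic_values(spec)


class TestLinearity:
    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_scaling_inputs_scales_trajectories(self, seed):
        lam = 2.5
        spec = generate_fixture_model(seed, n_constants=3, n_auxiliaries=5, n_delays=2)
        cfg = SimConfig(t_end=20)
        base = simulate(spec, cfg)
        scaled = simulate(scale_model(spec, lam), cfg)
        for name in base.series:
            assert np.allclose(scaled.series[name], lam * base.series[name], rtol=1e-12, atol=1e-9)

    def test_japan_superposition(self, japan, config):
        base = simulate(japan, config)
        scaled = simulate(scale_model(japan, 0.5), config)
        assert np.allclose(scaled.series[STOCK], 0.5 * base.series[STOCK], rtol=1e-12, atol=1e-9)

    @pytest.mark.parametrize("seed", range(0, 40, 5))
    def test_equilibrium_stationarity_on_fixtures(self, seed):
        """Equilibrium-initialized constant-input models sit still: constant
        auxiliaries, exactly linear stock."""
        spec = generate_fixture_model(seed, n_constants=3, n_auxiliaries=4, n_delays=3)
        traj = simulate(spec, SimConfig(t_end=20), delay_init="equilibrium")
        for v in spec.auxiliaries:
            assert np.ptp(traj.series[v.name]) == 0.0
        stock = spec.stocks[0]
        inflow = traj.series[stock.inflow][0]
        assert np.allclose(traj.series[stock.name], stock.initial + traj.times * inflow, rtol=1e-12, atol=1e-9)
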