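"""Engine semantics: target evaluation, synchronous stepping, attractor
enumeration and interval narrowing, cross-checked against a naive oracle."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalqn.qn_core import (
    Avg,
    Binary,
    BudgetExceededError,
    Const,
    NodeSummary,
    Perturbation,
    QNEvaluationError,
    QNModel,
    QNModelError,
    RelationshipDef,
    Unary,
    Var,
    VariableDef,
    enumerate_attractors,
    evaluate_formula,
    narrow_intervals,
    simulate,
    stabilize,
    summarize_variable,
    synchronous_step,
    target_value,
)
from clonalqn.synthetic_models import GeneratorConfig, fixtures, random_qn

from _oracle import naive_all_attractors, naive_step


def single_node(formula=None, constitutive=None, rng=(0, 4)):
    return QNModel(
        [VariableDef(1, "A", rng[0], rng[1], formula=formula, constitutive=constitutive)],
        [],
    )


def two_node(formula_a=None, formula_b=None):
    return QNModel(
        [
            VariableDef(1, "A", 0, 4, formula=formula_a),
            VariableDef(2, "B", 0, 4, formula=formula_b),
        ],
        [RelationshipDef(1, 2, "activator")],
    )


class TestFormulaEvaluation:
    @pytest.mark.parametrize(
        "expr, state, expected",
        [
            (Avg((Var("A"), Var("B"))), {"A": 4, "B": 2}, 3.0),
            (Const(2.5), {"A": 0, "B": 0}, 2.5),
            (Binary("-", Const(4), Avg((Var("A"),))), {"A": 2, "B": 0}, 2.0),
            (Binary("min", Const(2), Binary("*", Var("A"), Const(2))), {"A": 3, "B": 0}, 2.0),
            (Unary("ceil", Binary("/", Const(5), Const(2))), {"A": 0, "B": 0}, 3.0),
            (Unary("floor", Const(2.7)), {"A": 0, "B": 0}, 2.0),
            (Unary("neg", Var("B")), {"A": 0, "B": 3}, -3.0),
        ],
    )
    def test_expression_arithmetic(self, expr, state, expected):
        m = two_node()
        assert evaluate_formula(expr, state, m) == expected

    def test_division_by_zero_is_an_error(self):
        m = two_node()
        with pytest.raises(QNEvaluationError):
            evaluate_formula(Binary("/", Const(1), Var("A")), {"A": 0, "B": 0}, m)

    def test_unresolved_variable_is_a_model_error(self):
        m = two_node()
        with pytest.raises(QNModelError):
            evaluate_formula(Var("Nope"), {"A": 0, "B": 0}, m)

    def test_formula_referencing_non_input_rejected_at_build(self):
        # B's formula references A, but there is no A -> B relationship
        with pytest.raises(QNModelError):
            QNModel(
                [
                    VariableDef(1, "A", 0, 4),
                    VariableDef(2, "B", 0, 4, formula=Var("A")),
                ],
                [],
            )


class TestTargetValue:
    def test_default_function_averages_signed_inputs(self):
        # activators {4, 2}, inhibitor {2} -> 3 - 2 = 1
        m = QNModel(
            [
                VariableDef(1, "A", 0, 4),
                VariableDef(2, "B", 0, 4),
                VariableDef(3, "C", 0, 4),
                VariableDef(4, "T", 0, 4),
            ],
            [
                RelationshipDef(1, 4, "activator"),
                RelationshipDef(2, 4, "activator"),
                RelationshipDef(3, 4, "inhibitor"),
            ],
        )
        assert target_value("T", {"A": 4, "B": 2, "C": 2, "T": 0}, m) == 1.0

    def test_constitutive_minus_inhibition_when_no_activators(self):
        m = QNModel(
            [
                VariableDef(1, "I", 0, 4),
                VariableDef(2, "T", 0, 4, constitutive=4),
            ],
            [RelationshipDef(1, 2, "inhibitor")],
        )
        assert target_value("T", {"I": 4, "T": 0}, m) == 0.0

    def test_empty_inhibitor_set_contributes_zero(self):
        m = two_node()
        assert target_value("B", {"A": 1, "B": 0}, m) == 1.0

    def test_result_clamped_to_range(self):
        m = single_node(formula=Const(9.0))
        assert target_value("A", {"A": 0}, m) == 4.0

    def test_heterogeneous_input_rescaled_onto_consumer_range(self):
        # source range 0..2, consumer 0..4: level 1 maps to 2
        m = QNModel(
            [
                VariableDef(1, "S", 0, 2),
                VariableDef(2, "T", 0, 4),
            ],
            [RelationshipDef(1, 2, "activator")],
        )
        assert target_value("T", {"S": 1, "T": 0}, m) == 2.0


class TestSynchronousStep:
    def test_steps_toward_constant_target(self):
        m = single_node(formula=Const(4.0))
        assert synchronous_step((0,), m) == (1,)

    def test_fractional_target_forces_two_cycle(self):
        m = single_node(formula=Const(2.5))
        assert synchronous_step((2,), m) == (3,)
        assert synchronous_step((3,), m) == (2,)

    def test_perturbation_overrides_target(self):
        m = single_node(formula=Const(4.0))
        p = [Perturbation("A", "inhibit")]
        assert synchronous_step((0,), m, p) == (0,)

    def test_step_is_pure_and_deterministic(self):
        m = random_qn(GeneratorConfig(n_variables=5, seed=3))
        s = (1, 2, 0, 2, 1)
        assert synchronous_step(s, m) == synchronous_step(s, m)


class TestSimulate:
    def test_trajectory_to_fixed_point(self):
        m = single_node(formula=Const(4.0))
        traj, att = simulate((0,), m)
        assert [t[0] for t in traj[:5]] == [0, 1, 2, 3, 4]
        assert att.cycle == ((4,),)
        assert att.basin_witness == (0,)

    def test_fractional_oscillator_two_cycle(self):
        m = single_node(formula=Const(2.5))
        _, att = simulate((0,), m)
        assert att.period == 2
        assert att.states == {(2,), (3,)}

    def test_budget_exhaustion_is_explicit(self):
        m = single_node(formula=Const(4.0))
        with pytest.raises(BudgetExceededError):
            simulate((0,), m, max_steps=2)

    def test_mutual_inhibition_from_origin_reaches_center(self):
        fx = fixtures()["toggle"]
        _, att = simulate((0, 0), fx.model)
        assert att.cycle == ((2, 2),)


class TestEnumerateAttractors:
    def test_single_constant_node_has_one_fixed_point(self):
        m = single_node(formula=Const(3.0))
        atts = enumerate_attractors(m)
        assert len(atts) == 1 and next(iter(atts)).cycle == ((3,),)

    def test_fractional_oscillator_single_period_two(self):
        m = single_node(formula=Const(2.5))
        atts = enumerate_attractors(m)
        assert len(atts) == 1 and next(iter(atts)).period == 2

    def test_toggle_fixed_points_are_the_antidiagonal(self):
        fx = fixtures()["toggle"]
        atts = enumerate_attractors(fx.model)
        fps = {a.cycle[0] for a in atts if a.period == 1}
        assert fps == {(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)}

    def test_oversized_state_space_refused_with_size(self):
        m = random_qn(GeneratorConfig(n_variables=6, range_max=4, seed=0))
        with pytest.raises(BudgetExceededError, match=r"15625"):
            enumerate_attractors(m, bound=100)

    def test_matches_naive_oracle_on_random_models(self):
        for seed in range(10):
            m = random_qn(GeneratorConfig(n_variables=3, range_max=2, seed=seed))
            atts = enumerate_attractors(m)
            got = {
                frozenset(
                    tuple(sorted(zip((v.name for v in m.variables), st_)))
                    for st_ in a.cycle
                )
                for a in atts
            }
            assert got == naive_all_attractors(m), f"seed {seed}"


class TestNarrowIntervals:
    def test_constant_node_collapses_to_point(self):
        m = single_node(formula=Const(4.0))
        assert narrow_intervals(m) == {1: (4, 4)}

    def test_fractional_oscillator_narrows_to_band(self):
        m = single_node(formula=Const(2.5))
        assert narrow_intervals(m) == {1: (2, 3)}

    def test_toggle_box_contains_all_fixed_points(self):
        fx = fixtures()["toggle"]
        box = narrow_intervals(fx.model)
        assert box == {1: (0, 4), 2: (0, 4)}

    def test_perturbed_variable_is_a_point_interval(self):
        m = single_node(formula=Const(4.0))
        box = narrow_intervals(m, [Perturbation("A", "inhibit")])
        assert box == {1: (0, 0)}

    def test_order_does_not_change_the_fixpoint(self):
        rng = random.Random(7)
        for seed in range(20):
            m = random_qn(GeneratorConfig(n_variables=4, range_max=2, seed=seed))
            ref = narrow_intervals(m)
            order = [v.id for v in m.variables]
            rng.shuffle(order)
            assert narrow_intervals(m, order=order) == ref

    def test_point_box_is_a_fixed_point_of_the_step(self):
        for seed in range(30):
            m = random_qn(GeneratorConfig(n_variables=4, range_max=2, seed=seed))
            box = narrow_intervals(m)
            if all(lo == hi for lo, hi in box.values()):
                point = tuple(box[v.id][0] for v in m.variables)
                assert synchronous_step(point, m) == point


class TestSummaries:
    def test_oscillator_summary_is_mean_of_min_and_max(self):
        m = single_node(formula=Const(2.5))
        s = summarize_variable(m, (), "A")
        assert (s.min, s.max, s.midpoint) == (2, 3, 2.5)

    def test_point_stable_node(self):
        m = single_node(formula=Const(4.0))
        s = summarize_variable(m, (), "A")
        assert (s.min, s.max, s.midpoint) == (4, 4, 4.0)

    def test_forced_variable_summary_is_its_level(self):
        m = two_node()
        s = summarize_variable(m, [Perturbation("A", "force", 2)], "A")
        assert (s.min, s.max, s.midpoint) == (2, 2, 2.0)

    def test_summary_midpoint_of_point_equals_point(self):
        assert NodeSummary(3, 3).midpoint == 3.0

    def test_summaries_lie_within_narrowed_box(self):
        for seed in range(30):
            m = random_qn(GeneratorConfig(n_variables=4, range_max=2, seed=seed))
            box, summaries, _ = stabilize(m, seed=seed)
            for v in m.variables:
                lo, hi = box[v.id]
                s = summaries[v.name]
                assert lo <= s.min <= s.max <= hi


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    s0=st.lists(st.integers(0, 2), min_size=4, max_size=4),
)
def test_bounded_motion_and_range_invariant(seed, s0):
    """Each step moves every level by at most one and stays in range."""
    m = random_qn(GeneratorConfig(n_variables=4, range_max=2, seed=seed))
    s = tuple(s0)
    for _ in range(8):
        nxt = synchronous_step(s, m)
        for v, a, b in zip(m.variables, s, nxt):
            assert abs(a - b) <= 1
            assert v.range_min <= b <= v.range_max
        s = nxt


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), s0=st.lists(st.integers(0, 2), min_size=4, max_size=4))
def test_fixed_point_characterization(seed, s0):
    """A state is a period-1 attractor iff no variable's clamped target
    movement is nonzero."""
    m = random_qn(GeneratorConfig(n_variables=4, range_max=2, seed=seed))
    s = tuple(s0)
    is_fixed = synchronous_step(s, m) == s
    no_movement = True
    for i, v in enumerate(m.variables):
        t = target_value(v, s, m)
        if t > s[i] and s[i] < v.range_max:
            no_movement = False
        if t < s[i] and s[i] > v.range_min:
            no_movement = False
    assert is_fixed == no_movement


def test_engine_agrees_with_naive_stepper_on_breast_model(in_vivo):
    """One synchronous step of the full curated model matches the
    independent dict-based stepper from an arbitrary state."""
    state = {v.name: (v.id * 3) % (v.range_max + 1) for v in in_vivo.variables}
    got = synchronous_step(state, in_vivo)
    want = naive_step(in_vivo, state)
    assert {v.name: lvl for v, lvl in zip(in_vivo.variables, got)} == want
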