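"""Mutation operators: semantics, determinism, round-trip, detectability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nversion.compare import compare_grids
from nversion.engines import Agg, Const, Mul, Ref, Sum, evaluate_graph, render_formula
from nversion.inject import (
    InapplicableOperatorError,
    MutationOperator,
    apply_mutations,
    inject,
    operator_semantics,
    revert_mutations,
)

ALL_OPERATORS = list(MutationOperator)


def graph_for(op, named_graph, positional_graph):
    return named_graph if op is MutationOperator.INCORRECT_CELL_NAME else positional_graph


def test_logic_flip_turns_plus_into_minus():
    formula = Sum(((1, Ref("a")), (1, Ref("b"))))
    mutated = operator_semantics(MutationOperator.LOGIC, formula, seed=0)
    assert render_formula(mutated) == "a-b"


def test_typographical_perturbs_one_digit_of_one_constant():
    formula = Const(0.25)
    mutated = operator_semantics(MutationOperator.TYPOGRAPHICAL, formula, seed=1)
    assert isinstance(mutated, Const)
    assert mutated.value != 0.25
    # still a plausible single-digit slip: same order of magnitude class
    assert str(mutated.value) != "0.25"


def test_function_misuse_swaps_sum_for_mean_or_max():
    formula = Agg("SUM", tuple(f"R{i}C0" for i in range(4)))
    mutated = operator_semantics(MutationOperator.FUNCTION_MISUSE, formula, seed=3)
    assert isinstance(mutated, Agg)
    assert mutated.op in ("MEAN", "MAX")
    assert mutated.addrs == formula.addrs


def test_incorrect_range_extends_or_truncates_by_small_amount(positional_graph):
    agg_addrs = [
        a for a in positional_graph.grid_cell_addrs()
        if isinstance(positional_graph.cells[a], Agg)
    ]
    for seed in range(5):
        _, (mutation,) = inject(
            positional_graph, MutationOperator.INCORRECT_RANGE, seed=seed, k=1,
            eligible=agg_addrs,
        )
        old = mutation.old_formula
        new = mutation.new_formula
        assert isinstance(new, Agg)
        assert len(new.addrs) != len(old.addrs)
        assert abs(len(new.addrs) - len(old.addrs)) <= 3


def test_inapplicable_operator_signals_for_retry():
    with pytest.raises(InapplicableOperatorError):
        operator_semantics(MutationOperator.LOGIC, Const(1.0), seed=0)
    with pytest.raises(InapplicableOperatorError):
        operator_semantics(MutationOperator.INCORRECT_RANGE, Ref("a"), seed=0)
    with pytest.raises(InapplicableOperatorError):
        operator_semantics(MutationOperator.TYPOGRAPHICAL, Mul((Ref("a"), Ref("b"))), seed=0)


def test_mode_specificity_is_enforced(named_graph, positional_graph):
    with pytest.raises(ValueError, match="named"):
        inject(positional_graph, MutationOperator.INCORRECT_CELL_NAME, seed=0)
    with pytest.raises(ValueError, match="positional"):
        inject(named_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=0)
    with pytest.raises(ValueError, match="positional"):
        inject(named_graph, MutationOperator.MISCOPIED_FORMULA, seed=0)


def test_k_mutations_hit_k_distinct_cells(positional_graph):
    _, mutations = inject(positional_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=9, k=3)
    assert len(mutations) == 3
    assert len({m.target_cell for m in mutations}) == 3


def test_k_exceeding_eligible_cells_is_an_error(positional_graph):
    some_cell = next(iter(positional_graph.grid_cell_addrs()))
    with pytest.raises(ValueError, match="exceeds"):
        inject(positional_graph, MutationOperator.LOGIC, seed=0, k=2, eligible=[some_cell])


@pytest.mark.parametrize("operator", ALL_OPERATORS)
def test_apply_then_revert_restores_graph_exactly(operator, named_graph, positional_graph):
    graph = graph_for(operator, named_graph, positional_graph)
    mutated, mutations = inject(graph, operator, seed=21, k=2)
    restored = revert_mutations(mutated, mutations)
    assert restored.to_json_dict() == graph.to_json_dict()
    reapplied = apply_mutations(graph, mutations)
    assert reapplied.to_json_dict() == mutated.to_json_dict()


@pytest.mark.parametrize("operator", ALL_OPERATORS)
def test_injection_is_deterministic(operator, named_graph, positional_graph):
    graph = graph_for(operator, named_graph, positional_graph)
    _, log_a = inject(graph, operator, seed=33, k=2)
    _, log_b = inject(graph, operator, seed=33, k=2)
    assert [m.to_json_dict() for m in log_a] == [m.to_json_dict() for m in log_b]


def test_value_preserving_overwrite_is_invisible_to_comparison(
    positional_graph, clean_positional_grid
):
    """Overwriting a formula with the constant equal to its clean value is a
    documented blind spot: output comparison cannot detect it."""
    mutated, mutations = inject(
        positional_graph, MutationOperator.OVERWRITTEN_FORMULA, seed=5, k=1,
        overwrite_value="exact",
    )
    assert isinstance(mutations[0].new_formula, Const)
    report = compare_grids(evaluate_graph(mutated), clean_positional_grid)
    assert report.is_empty


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_seeded_reference_offsets_land_on_existing_cells(seed, positional_graph):
    mutated, (mutation,) = inject(
        positional_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=seed, k=1
    )
    assert mutation.detail["new_ref"] in positional_graph.cells
    evaluate_graph(mutated)  # never a broken reference by default


@pytest.mark.parametrize("operator", ALL_OPERATORS)
def test_output_changing_mutations_are_detected(
    operator, named_graph, positional_graph, clean_named_grid, clean_positional_grid
):
    """Ten seeded single mutations per operator: whenever the mutated grid
    differs from the clean one anywhere, cross-version comparison against
    the unmutated parallel version flags it."""
    graph = graph_for(operator, named_graph, positional_graph)
    parallel = (
        clean_positional_grid
        if operator is MutationOperator.INCORRECT_CELL_NAME
        else clean_named_grid
    )
    own_clean = (
        clean_named_grid
        if operator is MutationOperator.INCORRECT_CELL_NAME
        else clean_positional_grid
    )
    detected = 0
    for seed in range(10):
        mutated, _ = inject(graph, operator, seed=seed, k=1)
        grid = evaluate_graph(mutated)
        changed = not compare_grids(grid, own_clean, pair=("mutated", "clean")).is_empty
        report = compare_grids(grid, parallel, pair=("mutated", "parallel"))
        if changed:
            assert not report.is_empty
            detected += 1
        else:
            assert report.is_empty
    assert detected >= 1  # the operator is not a pure no-op generator
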