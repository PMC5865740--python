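"""Original-sin classification and error-count metrics."""

import pytest

from nversion.compare import compare_grids
from nversion.engines import Const, Ref, evaluate_graph, render_formula
from nversion.inject import Mutation, MutationOperator, apply_mutations, inject
from nversion.propagate import (
    ClassificationIntegrityError,
    classify,
    error_metrics,
    rate_summary,
)
from nversion.structure import build_structure, changed_cells

from conftest import bfs_downstream, manual_positional_graph, propagation_chain_graph


def _mutation(graph, addr, new_formula, operator=MutationOperator.OVERWRITTEN_FORMULA):
    return Mutation(
        operator=operator,
        target_cell=addr,
        detail={"old_formula": render_formula(graph.cells[addr]),
                "new_formula": render_formula(new_formula)},
        seed=0,
        old_formula=graph.cells[addr],
        new_formula=new_formula,
    )


def _classified(graph, mutations):
    mutated = apply_mutations(graph, mutations)
    report = compare_grids(evaluate_graph(mutated), evaluate_graph(graph),
                           pair=("mutated", "clean"))
    return classify(graph, mutations, report), report


def test_linear_chain_counts_one_original_three_propagated():
    """x1 -> x2 -> ... -> x5; a value-changing mutation at x2 is one
    original error with exactly x3, x4, x5 propagated (hand closure)."""
    graph = manual_positional_graph(
        5,
        (2009,),
        {(0, 0): Const(10.0), **{(i, 0): Ref(f"R{i-1}C0") for i in range(1, 5)}},
    )
    mutation = _mutation(graph, "R1C0", Const(99.0))
    cls, report = _classified(graph, [mutation])
    assert cls.originals == {("X1", 2009)}
    assert cls.propagated == {("X2", 2009), ("X3", 2009), ("X4", 2009)}
    assert cls.n_originals + cls.n_propagated == len(report)


def test_one_reference_error_propagating_over_ten_dependents():
    """The worked verification example: a single incorrect cell reference
    whose error travels through ten downstream health-state cells gives
    1 original + 10 propagated."""
    graph = propagation_chain_graph(n_dependents=10)
    target = graph.grid_addr[("X1", 2013)]
    mutated, mutations = inject(
        graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=2, k=1, eligible=[target]
    )
    report = compare_grids(evaluate_graph(mutated), evaluate_graph(graph),
                           pair=("mutated", "clean"))
    cls = classify(graph, mutations, report)
    assert cls.n_originals == 1
    assert cls.n_propagated == 10


def test_mutation_without_dependents_is_one_original_zero_propagated():
    graph = propagation_chain_graph(3)
    last = graph.grid_addr[("X4", 2013)]  # end of the chain
    mutation = _mutation(graph, last, Const(-1.0))
    cls, _ = _classified(graph, [mutation])
    assert cls.originals == {("X4", 2013)}
    assert cls.propagated == frozenset()


def test_zero_mutations_yield_empty_classification(positional_graph, clean_positional_grid):
    report = compare_grids(clean_positional_grid, clean_positional_grid)
    cls = classify(positional_graph, [], report)
    assert cls.n_originals == cls.n_propagated == 0


def test_classification_closure_matches_bfs_oracle(positional_graph, clean_positional_grid):
    """On the full model graph, classified propagated cells equal the
    independently BFS-computed downstream set intersected with the
    discrepant cells."""
    for seed in (1, 4, 8):
        mutated, mutations = inject(
            positional_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=seed, k=1
        )
        report = compare_grids(evaluate_graph(mutated), clean_positional_grid,
                               pair=("mutated", "clean"))
        cls = classify(positional_graph, mutations, report)
        target = mutations[0].target_cell
        downstream = bfs_downstream(positional_graph, target)
        expected = {
            positional_graph.addr_grid[a]
            for a in downstream
            if a in positional_graph.addr_grid
        } & set(report.addresses())
        expected -= cls.originals
        assert cls.propagated == expected


def test_unexplained_discrepancy_raises_integrity_error(positional_graph, clean_positional_grid):
    report = None
    for seed in range(20):  # find a seed whose mutation visibly changes output
        mutated, _ = inject(
            positional_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=seed, k=1
        )
        report = compare_grids(evaluate_graph(mutated), clean_positional_grid,
                               pair=("mutated", "clean"))
        if not report.is_empty:
            break
    assert report is not None and not report.is_empty
    with pytest.raises(ClassificationIntegrityError):
        classify(positional_graph, [], report)  # discrepancies, no known mutations


def test_partition_property_across_operators(named_graph, positional_graph,
                                             clean_named_grid, clean_positional_grid):
    for operator in MutationOperator:
        named = operator is MutationOperator.INCORRECT_CELL_NAME
        graph = named_graph if named else positional_graph
        clean = clean_named_grid if named else clean_positional_grid
        mutated, mutations = inject(graph, operator, seed=17, k=2)
        report = compare_grids(evaluate_graph(mutated), clean, pair=("mutated", "clean"))
        cls = classify(graph, mutations, report)
        assert cls.n_originals + cls.n_propagated == len(report)
        assert not (cls.originals & cls.propagated)


# ---------------------------------------------------------------------------
# rate metrics


def test_rate_summary_reproduces_headline_arithmetic():
    """58 originals over 2,208 changed cells is ~3%; 58 + 4,331 errors over
    15,420 model cells is ~28%; 147 total errors over 1,360 cells is 11%."""
    overall = rate_summary(58, 4331, 2208, 15420)
    assert overall["originals_per_changed_cell_pct"] == 3
    assert overall["total_errors_per_model_cell_pct"] == 28
    single_name_re_entry = rate_summary(1, 146, 76, 1360)
    assert single_name_re_entry["n_total_errors"] == 147
    assert single_name_re_entry["originals_per_changed_cell_pct"] == 1
    assert single_name_re_entry["total_errors_per_model_cell_pct"] == 11


def test_zero_errors_give_zero_rates():
    out = rate_summary(0, 0, 100, 1000)
    assert out["originals_per_changed_cell_pct"] == 0
    assert out["total_errors_per_model_cell_pct"] == 0


def test_originals_without_changed_cells_is_an_error():
    with pytest.raises(ValueError):
        rate_summary(3, 0, 0, 1000)


def test_error_metrics_uses_layout_and_changed_set(baseline_structure, positional_graph,
                                                   clean_positional_grid):
    re_entry = build_structure("RE_ENTRY")
    layout = positional_graph.layout
    mutated, mutations = inject(
        positional_graph, MutationOperator.INCORRECT_CELL_REFERENCE, seed=6, k=1
    )
    report = compare_grids(evaluate_graph(mutated), clean_positional_grid,
                           pair=("mutated", "clean"))
    cls = classify(positional_graph, mutations, report)
    changed = changed_cells(baseline_structure, re_entry, layout)
    metrics = error_metrics(cls, layout, changed)
    assert metrics["n_changed_cells"] == len(changed)
    assert metrics["n_total_cells"] == layout.n_cells
    assert metrics["n_original"] == cls.n_originals
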