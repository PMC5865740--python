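"""Shared fixtures: default model inputs, toy structures, and independent
oracles (brute-force projection, BFS reachability) used to cross-check the
engines and the classifier."""

from __future__ import annotations

import numpy as np
import pytest

from nversion.engines import (
    CellGrid,
    Const,
    FormulaGraph,
    Ref,
    compile_graph,
    evaluate_graph,
    formula_refs,
    run_matrix_engine,
)
from nversion.layout import GridLayout, RowSpec, default_layout
from nversion.parameters import CohortSchedule, ParameterSet, generate_parameters, generate_schedule
from nversion.structure import (
    CareStatus,
    HealthState,
    ModelStructure,
    Revision,
    Stage,
    build_structure,
)


@pytest.fixture(scope="session")
def baseline_structure():
    return build_structure("BASELINE")


@pytest.fixture(scope="session")
def baseline_params(baseline_structure):
    return generate_parameters(baseline_structure, seed=11)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=11)


@pytest.fixture(scope="session")
def named_graph(baseline_structure, baseline_params, schedule):
    return compile_graph(baseline_structure, baseline_params, schedule, mode="named")


@pytest.fixture(scope="session")
def positional_graph(baseline_structure, baseline_params, schedule):
    return compile_graph(baseline_structure, baseline_params, schedule, mode="positional")


@pytest.fixture(scope="session")
def clean_named_grid(named_graph):
    return evaluate_graph(named_graph)


@pytest.fixture(scope="session")
def clean_positional_grid(positional_graph):
    return evaluate_graph(positional_graph)


@pytest.fixture(scope="session")
def matrix_grid(baseline_structure, baseline_params, schedule):
    return run_matrix_engine(baseline_structure, baseline_params, schedule)


# ---------------------------------------------------------------------------
# toy models


def chain_structure(n_live: int = 3) -> ModelStructure:
    """Linear disease chain S0 -> S1 -> ... -> DEAD with self-loops."""
    states = [
        HealthState(f"S{i}", Stage.AIDS, CareStatus.NOT_ENGAGED) for i in range(n_live)
    ] + [HealthState("DEAD", Stage.DEAD_OTHER, CareStatus.DEAD)]
    transitions = {("DEAD", "DEAD")}
    for i in range(n_live):
        transitions.add((f"S{i}", f"S{i}"))
        nxt = f"S{i + 1}" if i + 1 < n_live else "DEAD"
        transitions.add((f"S{i}", nxt))
    s = ModelStructure(
        states=tuple(states),
        transitions=frozenset(transitions),
        entry_weights={"S0": 1.0},
        revision=Revision.BASELINE,
    )
    s.validate()
    return s


def chain_params(structure: ModelStructure, advance: float = 0.3) -> ParameterSet:
    probs: dict[str, dict[str, float]] = {}
    for sid in structure.state_ids:
        state = structure.state(sid)
        if state.is_dead:
            probs[sid] = {sid: 1.0}
            continue
        outs = sorted(t for (f, t) in structure.transitions if f == sid)
        nxt = [t for t in outs if t != sid][0]
        probs[sid] = {sid: 1.0 - advance, nxt: advance}
    p = ParameterSet(probs=probs)
    p.validate(structure)
    return p


def brute_force_counts(structure, params: ParameterSet, schedule: CohortSchedule):
    """Independent expected-count recursion: plain nested loops over
    cohorts x years x state pairs (no matrices, no formula graphs)."""
    ids = list(structure.state_ids)
    years = list(schedule.years)
    counts = {(s, y): 0.0 for s in ids for y in years}
    for j, _ in enumerate(years):
        vec = {
            s: schedule.entry_sizes[j] * structure.entry_weights.get(s, 0.0) for s in ids
        }
        for t in range(j, len(years)):
            year = years[t]
            if t > j:
                new = {s: 0.0 for s in ids}
                for frm in ids:
                    if vec[frm] == 0.0:
                        continue
                    for to in ids:
                        new[to] += vec[frm] * params.prob(frm, to, year)
                vec = new
            for s in ids:
                counts[(s, year)] += vec[s]
    return counts


def bfs_downstream(graph: FormulaGraph, start: str) -> set[str]:
    """Independent reachability oracle: breadth-first search over dependency
    edges recovered by re-scanning every formula (no networkx)."""
    dependents: dict[str, list[str]] = {}
    for addr, formula in graph.cells.items():
        for ref in formula_refs(formula):
            dependents.setdefault(ref, []).append(addr)
    seen: set[str] = set()
    frontier = [start]
    while frontier:
        cur = frontier.pop()
        for nxt in dependents.get(cur, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def manual_positional_graph(
    n_rows: int, years: tuple[int, ...], formulas: dict[tuple[int, int], object]
) -> FormulaGraph:
    """Hand-built positional graph over rows X0..X{n-1}: ``formulas`` maps
    (row index, year index) to a Formula node."""
    layout = GridLayout(
        rows=tuple(RowSpec(f"X{i}", "state") for i in range(n_rows)), years=years
    )
    grid_addr = {
        (f"X{i}", y): layout.positional_address(f"X{i}", y)
        for i in range(n_rows)
        for y in years
    }
    cells = {
        layout.positional_address(f"X{r}", years[c]): f for (r, c), f in formulas.items()
    }
    return FormulaGraph(
        mode="positional",
        cells=cells,
        layout=layout,
        grid_addr=grid_addr,
        addr_grid={a: k for k, a in grid_addr.items()},
    )


def propagation_chain_graph(n_dependents: int = 10) -> FormulaGraph:
    """A constants column feeding a linear dependency chain: cell (1, col 1)
    has exactly ``n_dependents`` cells downstream of it."""
    from nversion.engines import Mul, Sum

    n_rows = n_dependents + 2
    years = (2012, 2013)
    formulas: dict[tuple[int, int], object] = {}
    for i in range(n_rows):
        formulas[(i, 0)] = Const(1000.0 + 7.0 * i)
    # chain values are pairwise distinct and disjoint from the constants
    # column, so any misdirected reference visibly changes output
    formulas[(0, 1)] = Mul((Ref("R0C0"), Const(0.5)))
    for i in range(1, n_rows):
        formulas[(i, 1)] = Sum(((1, Ref(f"R{i - 1}C1")), (1, Const(float(i)))))
    return manual_positional_graph(n_rows, years, formulas)


def grid_from_values(values, years=None) -> CellGrid:
    """Ad-hoc grid for comparator/impact unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    years = tuple(years) if years is not None else tuple(2009 + j for j in range(values.shape[1]))
    layout = GridLayout(
        rows=tuple(RowSpec(f"X{i}", "state") for i in range(values.shape[0])), years=years
    )
    return CellGrid(layout=layout, values=values)
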