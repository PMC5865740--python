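"""Original vs propagated error accounting over the dependency graph.

The *original sin* rule counts an error only in the cell where it was
introduced; cells that are wrong merely because they depend on an erroneous
cell are tracked separately as *propagated* errors.  Given the ground-truth
mutation log, the discrepancy report of the mutated model against a clean
parallel version, and the formula dependency graph, discrepant cells
partition exactly into originals (mutated and themselves discrepant) and
propagated cells (discrepant, in the forward dependency closure of a
mutated cell, not themselves mutated).

A mutated cell whose value is unchanged (e.g. a value-preserving overwrite)
is an *undetectable original*: it is surfaced in the metrics but excluded
from the originals count, since output comparison only ever counts
identified discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .compare import DiscrepancyReport
from .engines import FormulaGraph, formula_refs
from .inject import Mutation
from .layout import GridLayout

__all__ = ["ErrorClassification", "ClassificationIntegrityError", "classify", "error_metrics", "rate_summary"]


class ClassificationIntegrityError(RuntimeError):
    """A discrepant cell is neither mutated nor downstream of a mutation --
    which signals an engine bug, not an injection effect."""


@dataclass(frozen=True)
class ErrorClassification:
    originals: frozenset[tuple[str, int]]
    propagated: frozenset[tuple[str, int]]
    undetectable_originals: frozenset[tuple[str, int]]
    per_operator: Mapping[str, int]  # originals per operator token

    @property
    def n_originals(self) -> int:
        return len(self.originals)

    @property
    def n_propagated(self) -> int:
        return len(self.propagated)

    @property
    def n_total(self) -> int:
        return self.n_originals + self.n_propagated


def classify(
    graph: FormulaGraph,
    mutations: Sequence[Mutation],
    report: DiscrepancyReport,
    state_rows_only: bool = False,
) -> ErrorClassification:
    """Partition the report's discrepant cells into originals and propagated.

    ``graph`` is the clean graph; closure edges are the union of its
    dependency edges and the edges induced by the mutated formulas (the
    union matters only for operators that rewire dependencies).  With
    ``state_rows_only`` the partition is restricted to health-state rows,
    excluding aggregate rows from both counts.
    """
    dg = graph.dependency_graph()
    for m in mutations:
        dg.add_edges_from((ref, m.target_cell) for ref in formula_refs(m.new_formula))

    discrepant = set(report.addresses())
    if state_rows_only:
        state_rows = set(graph.layout.state_rows)
        discrepant = {(label, y) for (label, y) in discrepant if label in state_rows}

    targets = [m.target_cell for m in mutations]
    target_keys = {m.target_cell: graph.addr_grid.get(m.target_cell) for m in mutations}

    originals: set[tuple[str, int]] = set()
    undetectable: set[tuple[str, int]] = set()
    per_operator: dict[str, int] = {}
    for m in mutations:
        key = target_keys[m.target_cell]
        if key is not None and key in discrepant:
            originals.add(key)
            per_operator[m.operator.value] = per_operator.get(m.operator.value, 0) + 1
        elif key is not None:
            undetectable.add(key)

    closure: set[str] = set()
    for t in targets:
        if t in dg:
            closure |= nx.descendants(dg, t)
    closure_keys = {graph.addr_grid.get(a) for a in closure} & {
        k for k in graph.grid_addr
    }

    propagated = (discrepant & closure_keys) - originals

    unexplained = discrepant - originals - propagated
    if unexplained:
        raise ClassificationIntegrityError(
            f"{len(unexplained)} discrepant cells are neither mutated nor downstream "
            f"of a mutation, e.g. {sorted(unexplained)[:3]}"
        )
    return ErrorClassification(
        originals=frozenset(originals),
        propagated=frozenset(propagated),
        undetectable_originals=frozenset(undetectable),
        per_operator=per_operator,
    )


def rate_summary(
    n_original: int, n_propagated: int, n_changed: int, n_total_cells: int
) -> dict:
    """Error-count metrics: originals per changed cell and total errors per
    model cell, rounded to integer percent for report parity.

    This is the arithmetic behind the headline error rates: e.g. 58
    originals over 2,208 changed cells is ~3%, and (58 + 4,331) errors over
    15,420 model cells is ~28%.
    """
    if n_changed == 0 and n_original > 0:
        raise ValueError("nonzero originals with an empty changed-cell set")
    if n_total_cells <= 0:
        raise ValueError("total cell count must be positive")
    originals_pct = 100.0 * n_original / n_changed if n_changed else 0.0
    total_pct = 100.0 * (n_original + n_propagated) / n_total_cells
    return {
        "n_original": int(n_original),
        "n_propagated": int(n_propagated),
        "n_total_errors": int(n_original + n_propagated),
        "n_changed_cells": int(n_changed),
        "n_total_cells": int(n_total_cells),
        "originals_per_changed_cell_pct": round(originals_pct),
        "total_errors_per_model_cell_pct": round(total_pct),
        "originals_per_changed_cell_pct_raw": originals_pct,
        "total_errors_per_model_cell_pct_raw": total_pct,
    }


def error_metrics(
    classification: ErrorClassification,
    layout: GridLayout,
    changed: Iterable[tuple[str, int]],
) -> dict:
    """Metrics record for one experiment, using the layout's cell count as
    the total-model-cells denominator and ``changed`` (from
    :func:`nversion.structure.changed_cells`) as the changed-cell set."""
    changed = set(changed)
    out = rate_summary(
        n_original=classification.n_originals,
        n_propagated=classification.n_propagated,
        n_changed=len(changed),
        n_total_cells=layout.n_cells,
    )
    out["n_undetectable_originals"] = len(classification.undetectable_originals)
    out["per_operator_originals"] = dict(classification.per_operator)
    return out
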