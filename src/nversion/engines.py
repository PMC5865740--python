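"""Three independent engines computing the same cohort projection.

The verification substrate is redundancy: the same multi-cohort
state-transition model is implemented three times, differing in how cells
are addressed and how the transition arithmetic is organized --

* **named** formula engine: a cell grid whose formulas reference other
  cells by user-style names (``AIDS_PRE@Y2012``, ``p.AIDS_PRE.ART_AIDS_Y1``);
* **positional** formula engine: structurally identical formulas, but every
  reference is a row/column coordinate (``R7C3``);
* **matrix** engine: per-cohort state vectors propagated by dense
  transition-matrix products (numpy), then projected into the same compact
  grid.

All three produce a :class:`CellGrid` over the same :class:`GridLayout`, so
cell-wise subtraction across engines is well defined.  The recursion each
implements is::

    count(s, t0)  = entry(t0) * w(s)
    count(s, t+1) = sum_from count(from, t) * P(from -> s)  +  entry(t+1) * w(s)

with aggregate rows as sums over their member state cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import networkx as nx
import numpy as np
import pandas as pd

from .layout import GridLayout, RowSpec, default_layout
from .parameters import CohortSchedule, ParameterSet
from .structure import ModelStructure

__all__ = [
    "Const",
    "Ref",
    "Sum",
    "Mul",
    "Agg",
    "Formula",
    "CellGrid",
    "FormulaGraph",
    "CompileError",
    "BrokenReferenceError",
    "compile_graph",
    "evaluate_graph",
    "run_matrix_engine",
    "expanded_cell_count",
    "formula_refs",
    "render_formula",
    "formula_to_json",
    "formula_from_json",
]


class CompileError(ValueError):
    pass


class BrokenReferenceError(KeyError):
    """A formula references an address that resolves to no cell."""


# ---------------------------------------------------------------------------
# formula AST (immutable; mutations build new trees)


@dataclass(frozen=True)
class Const:
    value: float


@dataclass(frozen=True)
class Ref:
    addr: str


@dataclass(frozen=True)
class Sum:
    """Signed sum: ``terms`` is a tuple of (sign, node) with sign in {+1, -1}."""

    terms: tuple[tuple[int, "Formula"], ...]


@dataclass(frozen=True)
class Mul:
    factors: tuple["Formula", ...]


AGG_OPS = ("SUM", "MEAN", "MAX")


@dataclass(frozen=True)
class Agg:
    """Range aggregation over an ordered list of cell addresses."""

    op: str
    addrs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.op not in AGG_OPS:
            raise ValueError(f"unknown range operator {self.op!r}")


Formula = Union[Const, Ref, Sum, Mul, Agg]


def formula_refs(formula: Formula) -> Iterator[str]:
    """All cell addresses a formula references, in syntactic order."""
    if isinstance(formula, Ref):
        yield formula.addr
    elif isinstance(formula, Sum):
        for _, node in formula.terms:
            yield from formula_refs(node)
    elif isinstance(formula, Mul):
        for node in formula.factors:
            yield from formula_refs(node)
    elif isinstance(formula, Agg):
        yield from formula.addrs


def render_formula(formula: Formula) -> str:
    """Human-readable formula string for audit logs and serialized graphs."""
    if isinstance(formula, Const):
        return repr(formula.value)
    if isinstance(formula, Ref):
        return formula.addr
    if isinstance(formula, Mul):
        return "*".join(_paren(f) for f in formula.factors)
    if isinstance(formula, Sum):
        parts: list[str] = []
        for i, (sign, node) in enumerate(formula.terms):
            txt = _paren(node)
            if i == 0:
                parts.append(txt if sign > 0 else f"-{txt}")
            else:
                parts.append(("+" if sign > 0 else "-") + txt)
        return "".join(parts) or "0"
    if isinstance(formula, Agg):
        return f"{formula.op}({','.join(formula.addrs)})"
    raise TypeError(type(formula))


def _paren(node: Formula) -> str:
    txt = render_formula(node)
    return f"({txt})" if isinstance(node, Sum) else txt


def formula_to_json(formula: Formula) -> dict:
    if isinstance(formula, Const):
        return {"t": "const", "v": formula.value}
    if isinstance(formula, Ref):
        return {"t": "ref", "a": formula.addr}
    if isinstance(formula, Sum):
        return {"t": "sum", "terms": [[s, formula_to_json(n)] for s, n in formula.terms]}
    if isinstance(formula, Mul):
        return {"t": "mul", "factors": [formula_to_json(n) for n in formula.factors]}
    if isinstance(formula, Agg):
        return {"t": "agg", "op": formula.op, "addrs": list(formula.addrs)}
    raise TypeError(type(formula))


def formula_from_json(obj: Mapping) -> Formula:
    t = obj["t"]
    if t == "const":
        return Const(float(obj["v"]))
    if t == "ref":
        return Ref(str(obj["a"]))
    if t == "sum":
        return Sum(tuple((int(s), formula_from_json(n)) for s, n in obj["terms"]))
    if t == "mul":
        return Mul(tuple(formula_from_json(n) for n in obj["factors"]))
    if t == "agg":
        return Agg(op=str(obj["op"]), addrs=tuple(str(a) for a in obj["addrs"]))
    raise ValueError(f"unknown formula node type {t!r}")


def _eval(formula: Formula, values: Mapping[str, float]) -> float:
    if isinstance(formula, Const):
        return formula.value
    if isinstance(formula, Ref):
        try:
            return values[formula.addr]
        except KeyError as exc:
            raise BrokenReferenceError(formula.addr) from exc
    if isinstance(formula, Sum):
        return sum(sign * _eval(node, values) for sign, node in formula.terms)
    if isinstance(formula, Mul):
        out = 1.0
        for node in formula.factors:
            out *= _eval(node, values)
        return out
    if isinstance(formula, Agg):
        try:
            vals = [values[a] for a in formula.addrs]
        except KeyError as exc:
            raise BrokenReferenceError(exc.args[0]) from exc
        if formula.op == "SUM":
            return float(sum(vals))
        if formula.op == "MEAN":
            return float(sum(vals) / len(vals)) if vals else 0.0
        return float(max(vals)) if vals else 0.0
    raise TypeError(type(formula))


# ---------------------------------------------------------------------------
# cell grid


@dataclass
class CellGrid:
    """Projected person-counts per (row, year) over a :class:`GridLayout`."""

    layout: GridLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_rows, self.layout.n_years):
            raise ValueError(
                f"values shape {self.values.shape} does not match layout "
                f"({self.layout.n_rows}, {self.layout.n_years})"
            )

    def value(self, label: str, year: int) -> float:
        return float(self.values[self.layout.row_index(label), self.layout.year_index(year)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index([r.label for r in self.layout.rows], name="row"),
            columns=list(self.layout.years),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellGrid":
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        layout = GridLayout(
            rows=tuple(RowSpec(str(label), "unknown") for label in frame.index),
            years=tuple(int(c) for c in frame.columns),
        )
        return cls(layout=layout, values=frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# formula graph


@dataclass
class FormulaGraph:
    """A spreadsheet: cell addresses mapped to formulas, plus the bijection
    between grid cells and (row label, year) coordinates.

    Formula nodes are immutable, so :meth:`copy` is a cheap dict copy and a
    mutation is a single-cell rebinding that leaves the original intact.
    """

    mode: str  # "named" | "positional"
    cells: dict[str, Formula]
    layout: GridLayout
    grid_addr: dict[tuple[str, int], str]
    addr_grid: dict[str, tuple[str, int]]
    meta: dict = field(default_factory=dict)

    def copy(self) -> "FormulaGraph":
        return FormulaGraph(
            mode=self.mode,
            cells=dict(self.cells),
            layout=self.layout,
            grid_addr=self.grid_addr,
            addr_grid=self.addr_grid,
            meta=self.meta,
        )

    def dependency_graph(self) -> nx.DiGraph:
        """Directed graph with an edge referenced -> referencing cell."""
        g = nx.DiGraph()
        g.add_nodes_from(self.cells)
        for addr, formula in self.cells.items():
            for ref in formula_refs(formula):
                g.add_edge(ref, addr)
        return g

    def grid_cell_addrs(self) -> Iterable[str]:
        return self.grid_addr.values()

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "cells": {a: render_formula(f) for a, f in sorted(self.cells.items())},
        }


def _addressing(structure: ModelStructure, params: ParameterSet, layout: GridLayout, mode: str):
    """Return (grid, param, weight, entry) address builders for a mode."""
    ids = structure.state_ids
    sidx = {s: i for i, s in enumerate(ids)}
    n_states = len(ids)
    tv_years = sorted(params.time_varying)
    param_origin = layout.n_rows + 1  # leave one blank sheet row below the grid

    if mode == "named":

        def grid(label: str, year: int) -> str:
            return layout.named_address(label, year)

        def param(frm: str, to: str, year: int | None) -> str:
            return f"p.{frm}.{to}" if year is None else f"p.{frm}.{to}.{year}"

        def weight(sid: str) -> str:
            return f"w.{sid}"

    elif mode == "positional":

        def grid(label: str, year: int) -> str:
            return layout.positional_address(label, year)

        def param(frm: str, to: str, year: int | None) -> str:
            block = 0 if year is None else 1 + tv_years.index(year)
            return f"R{param_origin + sidx[frm]}C{block * n_states + sidx[to]}"

        def weight(sid: str) -> str:
            return f"R{param_origin + n_states}C{sidx[sid]}"

    else:
        raise CompileError(f"unknown addressing mode {mode!r}")

    def entry(year: int) -> str:
        return grid("ENTRIES", year)

    return grid, param, weight, entry


def compile_graph(
    structure: ModelStructure,
    params: ParameterSet,
    schedule: CohortSchedule,
    mode: str = "named",
    layout: GridLayout | None = None,
) -> FormulaGraph:
    """Compile the projection into a :class:`FormulaGraph`.

    The named and positional compilations are structurally identical up to
    addressing: every health-state cell carries a single formula encoding
    all inflows to that state, aggregate rows are sum-over-range formulas,
    and transition probabilities / entry weights live in constant cells the
    formulas reference (a parameter block below the grid in positional
    mode).
    """
    params.validate(structure)
    years = schedule.years
    if layout is None:
        layout = default_layout(structure, years)
    if tuple(layout.years) != tuple(years):
        raise CompileError("layout years do not match schedule years")
    if "ENTRIES" not in {r.label for r in layout.rows}:
        raise CompileError("layout lacks the ENTRIES row")
    missing = [s for s in structure.state_ids if s not in {r.label for r in layout.rows}]
    if missing:
        raise CompileError(f"layout lacks state rows {missing}")

    grid, param, weight, entry = _addressing(structure, params, layout, mode)
    tv = params.time_varying

    def param_addr(frm: str, to: str, year: int) -> str:
        if year in tv and frm in tv[year]:
            return param(frm, to, year)
        return param(frm, to, None)

    cells: dict[str, Formula] = {}

    # parameter block (constants)
    for frm, to in sorted(structure.transitions):
        cells[param(frm, to, None)] = Const(params.probs[frm].get(to, 0.0))
    for year in sorted(tv):
        for frm in sorted(tv[year]):
            for to, p in sorted(tv[year][frm].items()):
                cells[param(frm, to, year)] = Const(p)
    for sid in structure.entry_weights:
        cells[weight(sid)] = Const(structure.entry_weights[sid])

    inflows: dict[str, list[str]] = {sid: [] for sid in structure.state_ids}
    for frm, to in sorted(structure.transitions):
        inflows[to].append(frm)

    entry_states = set(structure.entry_weights)
    for t_idx, year in enumerate(years):
        cells[entry(year)] = Const(schedule.entry_sizes[t_idx])
        for sid in structure.state_ids:
            addr = grid(sid, year)
            entry_term = (
                Mul((Ref(entry(year)), Ref(weight(sid)))) if sid in entry_states else None
            )
            if t_idx == 0:
                cells[addr] = entry_term if entry_term is not None else Const(0.0)
            else:
                prev = years[t_idx - 1]
                terms: list[tuple[int, Formula]] = [
                    (1, Mul((Ref(grid(frm, prev)), Ref(param_addr(frm, sid, year)))))
                    for frm in inflows[sid]
                ]
                if entry_term is not None:
                    terms.append((1, entry_term))
                cells[addr] = Sum(tuple(terms))
        for row in layout.rows:
            if row.kind == "aggregate":
                cells[grid(row.label, year)] = Agg(
                    "SUM", tuple(grid(m, year) for m in row.members)
                )

    grid_addr = {(r.label, y): grid(r.label, y) for r in layout.rows for y in years}
    addr_grid = {a: k for k, a in grid_addr.items()}
    graph = FormulaGraph(
        mode=mode,
        cells=cells,
        layout=layout,
        grid_addr=grid_addr,
        addr_grid=addr_grid,
        meta={"revision": structure.revision.value, "n_states": len(structure.state_ids)},
    )
    # sanity: compilation must be acyclic
    dg = graph.dependency_graph()
    if not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        raise CompileError(f"internal error: compiled graph is cyclic ({cycle})")
    unresolved = sorted(set(dg.nodes) - set(cells))
    if unresolved:
        raise CompileError(f"unresolvable references: {unresolved[:5]}")
    return graph


def evaluate_graph(graph: FormulaGraph, order: Iterable[str] | None = None) -> CellGrid:
    """Evaluate every cell once in topological order and project the grid.

    ``order`` may supply an alternative topological order; the result is
    independent of tie-breaking among ready cells.  A reference to a missing
    cell (possible after mutation with out-of-grid offsets enabled) raises
    :class:`BrokenReferenceError`.
    """
    if order is None:
        dg = graph.dependency_graph()
        if not nx.is_directed_acyclic_graph(dg):
            raise CompileError("graph is cyclic; cannot evaluate")
        order = nx.topological_sort(dg)
    values: dict[str, float] = {}
    for addr in order:
        formula = graph.cells.get(addr)
        if formula is None:
            raise BrokenReferenceError(addr)
        values[addr] = _eval(formula, values)
    out = np.empty((graph.layout.n_rows, graph.layout.n_years))
    for (label, year), addr in graph.grid_addr.items():
        out[graph.layout.row_index(label), graph.layout.year_index(year)] = values[addr]
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite cell values after evaluation")
    return CellGrid(layout=graph.layout, values=out)


# ---------------------------------------------------------------------------
# matrix engine


def run_matrix_engine(
    structure: ModelStructure,
    params: ParameterSet,
    schedule: CohortSchedule,
    layout: GridLayout | None = None,
) -> CellGrid:
    """Propagate each entering cohort by annual matrix-vector products and
    project the summed calendar-year counts into the compact layout."""
    params.validate(structure)
    years = schedule.years
    if layout is None:
        layout = default_layout(structure, years)
    ids = structure.state_ids
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    T = len(years)

    w = np.zeros(n)
    for sid, wt in structure.entry_weights.items():
        w[idx[sid]] = wt

    matrices = {year: params.matrix(structure, year) for year in years}
    for year, P in matrices.items():
        sums = P.sum(axis=1)
        if not np.allclose(sums, 1.0, rtol=0.0, atol=1e-9):
            bad = [ids[i] for i in np.where(np.abs(sums - 1.0) > 1e-9)[0]]
            raise ValueError(f"non-stochastic matrix rows for year {year}: {bad}")

    counts = np.zeros((n, T))
    for j in range(T):  # cohort entering in year index j
        v = schedule.entry_sizes[j] * w
        counts[:, j] += v
        for t in range(j + 1, T):
            v = v @ matrices[years[t]]
            counts[:, t] += v

    values = np.zeros((layout.n_rows, layout.n_years))
    for r, row in enumerate(layout.rows):
        if row.kind == "state":
            values[r, :] = counts[idx[row.label], :] if row.label in idx else 0.0
        elif row.kind == "aggregate":
            values[r, :] = sum(counts[idx[m], :] for m in row.members)
        elif row.kind == "entry":
            values[r, :] = np.asarray(schedule.entry_sizes)
    return CellGrid(layout=layout, values=values)


def expanded_cell_count(structure: ModelStructure, schedule: CohortSchedule) -> int:
    """Cell count of the matrix engine's expanded representation: one
    transition matrix per year plus one state vector per (cohort, year)
    pair it lives through.  Always larger than the compact grid."""
    n = len(structure.state_ids)
    T = schedule.n_years
    vector_cells = n * sum(T - j for j in range(T))
    return n * n * T + vector_cells
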