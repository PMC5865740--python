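"""Mutation operators simulating unintentional spreadsheet errors.

The taxonomy covers the error classes observed when a single programmer
revises a cell-formula model: incorrect cell names, incorrect cell
references, incorrect ranges in a formula, incorrectly copied formulae,
overwritten formulae, misuse of built-in functions, plus typographical and
logic slips.  This module *simulates* such errors with seeded sampling over
eligible cells -- it is a model of human error, not a measurement of it --
and records a ground-truth log so detection and classification can be
tested against known injections.

Operator/mode applicability mirrors the addressing semantics: name
rebinding only makes sense in the named version; reference offsets and
relative-copy mistakes only in the positional version.

Mutations are value-level rebindings of a single cell's formula; applying
then reverting a mutation restores the original graph exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .engines import (
    Agg,
    Const,
    Formula,
    FormulaGraph,
    Mul,
    Ref,
    Sum,
    evaluate_graph,
    formula_refs,
    render_formula,
)

__all__ = [
    "MutationOperator",
    "Mutation",
    "InapplicableOperatorError",
    "inject",
    "operator_semantics",
    "apply_mutations",
    "revert_mutations",
]


class MutationOperator(str, Enum):
    INCORRECT_CELL_NAME = "INCORRECT_CELL_NAME"
    INCORRECT_CELL_REFERENCE = "INCORRECT_CELL_REFERENCE"
    INCORRECT_RANGE = "INCORRECT_RANGE"
    MISCOPIED_FORMULA = "MISCOPIED_FORMULA"
    OVERWRITTEN_FORMULA = "OVERWRITTEN_FORMULA"
    FUNCTION_MISUSE = "FUNCTION_MISUSE"
    TYPOGRAPHICAL = "TYPOGRAPHICAL"
    LOGIC = "LOGIC"


#: Operators only meaningful for one addressing mode.
_NAMED_ONLY = {MutationOperator.INCORRECT_CELL_NAME}
_POSITIONAL_ONLY = {MutationOperator.INCORRECT_CELL_REFERENCE, MutationOperator.MISCOPIED_FORMULA}


class InapplicableOperatorError(ValueError):
    """Operator cannot act on this cell/formula; the sampler retries."""


@dataclass(frozen=True)
class Mutation:
    operator: MutationOperator
    target_cell: str
    detail: dict
    seed: int
    old_formula: Formula
    new_formula: Formula

    def to_json_dict(self) -> dict:
        from .engines import formula_to_json

        return {
            "operator": self.operator.value,
            "target_cell": self.target_cell,
            "detail": self.detail,
            "seed": self.seed,
            "old_formula": formula_to_json(self.old_formula),
            "new_formula": formula_to_json(self.new_formula),
        }

    @classmethod
    def from_json_dict(cls, obj: dict) -> "Mutation":
        from .engines import formula_from_json

        return cls(
            operator=MutationOperator(obj["operator"]),
            target_cell=obj["target_cell"],
            detail=dict(obj["detail"]),
            seed=int(obj["seed"]),
            old_formula=formula_from_json(obj["old_formula"]),
            new_formula=formula_from_json(obj["new_formula"]),
        )


# ---------------------------------------------------------------------------
# formula surgery helpers


def _positions_of(formula: Formula, kind) -> list[tuple[int, ...]]:
    """Paths to all nodes of a given type, in deterministic syntactic order."""
    out: list[tuple[int, ...]] = []

    def walk(node: Formula, path: tuple[int, ...]) -> None:
        if isinstance(node, kind):
            out.append(path)
        if isinstance(node, Sum):
            for i, (_, child) in enumerate(node.terms):
                walk(child, path + (i,))
        elif isinstance(node, Mul):
            for i, child in enumerate(node.factors):
                walk(child, path + (i,))

    walk(formula, ())
    return out


def _get(formula: Formula, path: tuple[int, ...]) -> Formula:
    node = formula
    for i in path:
        node = node.terms[i][1] if isinstance(node, Sum) else node.factors[i]
    return node


def _replace(formula: Formula, path: tuple[int, ...], new: Formula) -> Formula:
    if not path:
        return new
    i, rest = path[0], path[1:]
    if isinstance(formula, Sum):
        terms = list(formula.terms)
        sign, child = terms[i]
        terms[i] = (sign, _replace(child, rest, new))
        return Sum(tuple(terms))
    if isinstance(formula, Mul):
        factors = list(formula.factors)
        factors[i] = _replace(factors[i], rest, new)
        return Mul(tuple(factors))
    raise TypeError(type(formula))


_POS_RE = re.compile(r"^R(\d+)C(\d+)$")


def _shift_addr(addr: str, dr: int, dc: int) -> str:
    m = _POS_RE.match(addr)
    if not m:
        raise InapplicableOperatorError(f"address {addr!r} is not positional")
    r, c = int(m.group(1)) + dr, int(m.group(2)) + dc
    if r < 0 or c < 0:
        raise InapplicableOperatorError("offset leaves the sheet")
    return f"R{r}C{c}"


def _shift_formula(formula: Formula, dr: int, dc: int) -> Formula:
    if isinstance(formula, Const):
        return formula
    if isinstance(formula, Ref):
        return Ref(_shift_addr(formula.addr, dr, dc))
    if isinstance(formula, Sum):
        return Sum(tuple((s, _shift_formula(n, dr, dc)) for s, n in formula.terms))
    if isinstance(formula, Mul):
        return Mul(tuple(_shift_formula(n, dr, dc) for n in formula.factors))
    if isinstance(formula, Agg):
        return Agg(formula.op, tuple(_shift_addr(a, dr, dc) for a in formula.addrs))
    raise TypeError(type(formula))


def _perturb_digit(value: float, rng: np.random.Generator) -> float:
    """Replace one digit of the decimal rendering with a different digit."""
    s = f"{value:.12g}"
    digit_positions = [i for i, ch in enumerate(s) if ch.isdigit()]
    for _ in range(32):
        pos = int(rng.choice(digit_positions))
        new_digit = str(int(rng.integers(0, 10)))
        if s[pos] == new_digit:
            continue
        candidate = s[:pos] + new_digit + s[pos + 1 :]
        try:
            out = float(candidate)
        except ValueError:
            continue
        if out != value and np.isfinite(out):
            return out
    raise InapplicableOperatorError(f"no digit perturbation found for {value!r}")


# ---------------------------------------------------------------------------
# per-operator semantics


class _Ctx:
    """Context handed to operator implementations."""

    def __init__(self, graph: FormulaGraph, addr: str, forbidden: frozenset[str], clean_value=None):
        self.graph = graph
        self.addr = addr
        self.forbidden = forbidden  # addresses that would create a cycle
        self.clean_value = clean_value


def _op_incorrect_cell_name(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    ref_paths = _positions_of(formula, Ref)
    if not ref_paths:
        raise InapplicableOperatorError("formula has no named reference")
    rng.shuffle(ref_paths)
    all_addrs = ctx.graph.cells.keys()
    for path in ref_paths:
        old = _get(formula, path).addr
        prefix = old.split(".", 1)[0] + "." if "." in old else None
        if prefix:  # rebind parameter/weight names within their namespace
            candidates = [a for a in all_addrs if a.startswith(prefix) and a != old]
        else:  # grid names rebind to other grid names
            candidates = [a for a in all_addrs if "." not in a and a != old]
        candidates = sorted(set(candidates) - ctx.forbidden - {ctx.addr})
        if not candidates:
            continue
        new = candidates[int(rng.integers(0, len(candidates)))]
        return (
            _replace(formula, path, Ref(new)),
            {"kind": "rebind", "old_ref": old, "new_ref": new},
        )
    raise InapplicableOperatorError("no safe rebinding found")


def _op_incorrect_cell_reference(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    ref_paths = _positions_of(formula, Ref)
    if not ref_paths:
        raise InapplicableOperatorError("formula has no reference")
    rng.shuffle(ref_paths)
    allow_broken = ctx.graph.meta.get("allow_broken_refs", False)
    for path in ref_paths:
        old = _get(formula, path).addr
        for _ in range(64):
            dr, dc = int(rng.integers(-3, 4)), int(rng.integers(-3, 4))
            if dr == 0 and dc == 0:
                continue
            try:
                new = _shift_addr(old, dr, dc)
            except InapplicableOperatorError:
                continue
            if new == old or new == ctx.addr or new in ctx.forbidden:
                continue
            if new not in ctx.graph.cells and not allow_broken:
                continue
            return (
                _replace(formula, path, Ref(new)),
                {"kind": "offset", "old_ref": old, "new_ref": new, "offset": [dr, dc]},
            )
    raise InapplicableOperatorError("no valid reference offset found")


def _op_incorrect_range(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    if not isinstance(formula, Agg):
        raise InapplicableOperatorError("formula has no range")
    graph = ctx.graph
    extend_candidates: list[str] = []
    last = formula.addrs[-1]
    key = graph.addr_grid.get(last)
    if key is not None:
        label, year = key
        r = graph.layout.row_index(label)
        if r + 1 < graph.layout.n_rows:
            nxt_label = graph.layout.rows[r + 1].label
            nxt = graph.grid_addr[(nxt_label, year)]
            if nxt not in formula.addrs and nxt not in ctx.forbidden and nxt != ctx.addr:
                extend_candidates.append(nxt)
    moves = []
    if len(formula.addrs) > 1:
        moves.append("truncate")
    if extend_candidates:
        moves.append("extend")
    if not moves:
        raise InapplicableOperatorError("range can be neither extended nor truncated")
    move = moves[int(rng.integers(0, len(moves)))]
    if move == "truncate":
        k = int(rng.integers(1, min(3, len(formula.addrs) - 1) + 1))
        new = Agg(formula.op, formula.addrs[:-k])
        detail = {"kind": "truncate", "dropped": list(formula.addrs[-k:])}
    else:
        new = Agg(formula.op, formula.addrs + (extend_candidates[0],))
        detail = {"kind": "extend", "added": [extend_candidates[0]]}
    return new, detail


def _op_miscopied_formula(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    graph = ctx.graph
    key = graph.addr_grid.get(ctx.addr)
    if key is None:
        raise InapplicableOperatorError("target is not a grid cell")
    label, year = key
    r, c = graph.layout.row_index(label), graph.layout.year_index(year)
    neighbors = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    rng.shuffle(neighbors)
    for nr, nc in neighbors:
        try:
            nb_label, nb_year = graph.layout.cell_from_positional(nr, nc)
        except KeyError:
            continue
        nb_addr = graph.grid_addr[(nb_label, nb_year)]
        nb_formula = graph.cells.get(nb_addr)
        if nb_formula is None or isinstance(nb_formula, Const):
            continue
        try:
            copied = _shift_formula(nb_formula, r - nr, c - nc)
        except InapplicableOperatorError:
            continue
        refs = set(formula_refs(copied))
        if not refs <= set(graph.cells):
            continue
        if refs & ctx.forbidden or ctx.addr in refs:
            continue
        if copied == formula:
            continue
        return copied, {"kind": "relative_copy", "source": nb_addr}
    raise InapplicableOperatorError("no copyable neighbor found")


def _op_overwritten_formula(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    if isinstance(formula, Const):
        raise InapplicableOperatorError("cell already holds a constant")
    if ctx.clean_value is None:
        raise InapplicableOperatorError("clean value unavailable")
    mode = ctx.graph.meta.get("overwrite_value", "scaled")
    if mode == "exact":
        value = float(ctx.clean_value)
    else:
        value = float(ctx.clean_value) * float(rng.uniform(0.5, 1.5))
    return Const(value), {"kind": "overwrite", "constant": value, "value_mode": mode}


def _op_function_misuse(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    if not isinstance(formula, Agg) or formula.op != "SUM":
        raise InapplicableOperatorError("formula has no SUM range function")
    new_op = ("MEAN", "MAX")[int(rng.integers(0, 2))]
    return Agg(new_op, formula.addrs), {"kind": "op_swap", "old_op": "SUM", "new_op": new_op}


def _op_typographical(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    const_paths = _positions_of(formula, Const)
    if not const_paths:
        raise InapplicableOperatorError("formula has no constant")
    path = const_paths[int(rng.integers(0, len(const_paths)))]
    old = _get(formula, path)
    new_value = _perturb_digit(old.value, rng)
    return (
        _replace(formula, path, Const(new_value)),
        {"kind": "digit", "old_value": old.value, "new_value": new_value},
    )


def _op_logic(formula: Formula, rng: np.random.Generator, ctx: _Ctx):
    if not isinstance(formula, Sum) or len(formula.terms) < 2:
        raise InapplicableOperatorError("formula has no flippable +/- operator")
    i = int(rng.integers(1, len(formula.terms)))  # first term has no leading operator
    terms = list(formula.terms)
    sign, node = terms[i]
    terms[i] = (-sign, node)
    return Sum(tuple(terms)), {"kind": "sign_flip", "term_index": i}


_OPERATORS: dict[MutationOperator, Callable] = {
    MutationOperator.INCORRECT_CELL_NAME: _op_incorrect_cell_name,
    MutationOperator.INCORRECT_CELL_REFERENCE: _op_incorrect_cell_reference,
    MutationOperator.INCORRECT_RANGE: _op_incorrect_range,
    MutationOperator.MISCOPIED_FORMULA: _op_miscopied_formula,
    MutationOperator.OVERWRITTEN_FORMULA: _op_overwritten_formula,
    MutationOperator.FUNCTION_MISUSE: _op_function_misuse,
    MutationOperator.TYPOGRAPHICAL: _op_typographical,
    MutationOperator.LOGIC: _op_logic,
}


def operator_semantics(
    operator: MutationOperator | str,
    formula: Formula,
    seed: int,
    context: _Ctx | None = None,
) -> Formula:
    """Apply one operator to one formula (seeded); returns the mutated formula.

    Raises :class:`InapplicableOperatorError` when the formula lacks the
    feature the operator needs, so samplers can retry another cell.
    Operators that need graph context (reference offsets, relative copies,
    overwrites) require ``context``.
    """
    operator = MutationOperator(operator)
    rng = np.random.default_rng(seed)
    if context is None:
        context = _Ctx(graph=_DUMMY_GRAPH, addr="", forbidden=frozenset())
    new_formula, _ = _OPERATORS[operator](formula, rng, context)
    return new_formula


class _EmptyLayoutGraph:
    cells: dict = {}
    meta: dict = {}
    addr_grid: dict = {}
    grid_addr: dict = {}


_DUMMY_GRAPH = _EmptyLayoutGraph()


def _eligible_cells(graph: FormulaGraph, operator: MutationOperator) -> list[str]:
    """Grid cells whose formulas carry the feature the operator needs."""
    out = []
    for addr in graph.grid_cell_addrs():
        f = graph.cells[addr]
        if operator is MutationOperator.LOGIC:
            ok = isinstance(f, Sum) and len(f.terms) >= 2
        elif operator is MutationOperator.TYPOGRAPHICAL:
            ok = bool(_positions_of(f, Const))
        elif operator in (MutationOperator.INCORRECT_RANGE, MutationOperator.FUNCTION_MISUSE):
            ok = isinstance(f, Agg)
        elif operator is MutationOperator.OVERWRITTEN_FORMULA:
            ok = not isinstance(f, Const)
        elif operator is MutationOperator.MISCOPIED_FORMULA:
            ok = not isinstance(f, Const)
        else:  # reference/name rebinding
            ok = bool(_positions_of(f, Ref)) or isinstance(f, Agg)
        if ok:
            out.append(addr)
    return out


def inject(
    graph: FormulaGraph,
    operator: MutationOperator | str,
    seed: int,
    k: int = 1,
    eligible: Sequence[str] | None = None,
    overwrite_value: str = "scaled",
    allow_broken_refs: bool = False,
) -> tuple[FormulaGraph, list[Mutation]]:
    """Inject exactly ``k`` original mutations at ``k`` distinct cells.

    Sampling is seeded and uniform over eligible cells; cells where the
    operator turns out to be inapplicable (or would create a cyclic or
    broken reference) are skipped and another cell drawn.  The input graph
    is never modified; the mutated copy and the ground-truth log are
    returned.

    ``overwrite_value='exact'`` makes OVERWRITTEN_FORMULA paste the
    formula's current clean value -- a value-preserving overwrite that no
    output comparison can detect, documenting a known blind spot of the
    method.  ``allow_broken_refs`` lets reference offsets land outside the
    sheet (off by default; spreadsheets rarely produce hard failures).
    """
    operator = MutationOperator(operator)
    if operator in _NAMED_ONLY and graph.mode != "named":
        raise ValueError(f"{operator.value} applies only to named graphs")
    if operator in _POSITIONAL_ONLY and graph.mode != "positional":
        raise ValueError(f"{operator.value} applies only to positional graphs")

    rng = np.random.default_rng(seed)
    pool = list(eligible) if eligible is not None else _eligible_cells(graph, operator)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds {len(pool)} eligible cells")
    order = list(rng.permutation(len(pool)))

    clean_values: dict[str, float] | None = None
    if operator is MutationOperator.OVERWRITTEN_FORMULA:
        grid = evaluate_graph(graph)
        clean_values = {
            addr: grid.value(label, year) for (label, year), addr in graph.grid_addr.items()
        }

    dg = graph.dependency_graph()
    mutated = graph.copy()
    mutated.meta = dict(graph.meta, overwrite_value=overwrite_value, allow_broken_refs=allow_broken_refs)
    mutations: list[Mutation] = []
    for idx in order:
        if len(mutations) >= k:
            break
        addr = pool[idx]
        old_formula = mutated.cells[addr]
        forbidden = frozenset(nx.descendants(dg, addr)) if addr in dg else frozenset()
        ctx = _Ctx(
            graph=mutated,
            addr=addr,
            forbidden=forbidden,
            clean_value=None if clean_values is None else clean_values.get(addr),
        )
        try:
            new_formula, detail = _OPERATORS[operator](old_formula, rng, ctx)
        except InapplicableOperatorError:
            continue
        mutated.cells[addr] = new_formula
        # keep the cycle guard current as dependencies are rewired
        dg.remove_edges_from(list(dg.in_edges(addr)))
        dg.add_edges_from((ref, addr) for ref in formula_refs(new_formula) if ref in dg)
        mutations.append(
            Mutation(
                operator=operator,
                target_cell=addr,
                detail={
                    **detail,
                    "old_formula": render_formula(old_formula),
                    "new_formula": render_formula(new_formula),
                },
                seed=seed,
                old_formula=old_formula,
                new_formula=new_formula,
            )
        )
    if len(mutations) < k:
        # roll back: the contract is exactly k or an error
        raise ValueError(
            f"only {len(mutations)} of {k} requested {operator.value} mutations were applicable"
        )
    return mutated, mutations


def apply_mutations(graph: FormulaGraph, mutations: Iterable[Mutation]) -> FormulaGraph:
    out = graph.copy()
    for m in mutations:
        if m.target_cell not in out.cells:
            raise KeyError(m.target_cell)
        out.cells[m.target_cell] = m.new_formula
    return out


def revert_mutations(graph: FormulaGraph, mutations: Iterable[Mutation]) -> FormulaGraph:
    out = graph.copy()
    for m in mutations:
        out.cells[m.target_cell] = m.old_formula
    return out
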