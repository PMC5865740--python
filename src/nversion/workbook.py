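"""XLSX workbook reading/writing for retrospective verification.

The deposited model workbooks hold the three versions as tabs
(``Model (SN)``, ``Model (SC)``, ``Model (Matrix)``) plus pairwise diff
tabs, in before/after-correction pairs per revision.  This module extracts
compact grids (and formula texts where present) from such workbooks so the
comparator, classifier and impact metrics can be replayed on them, and
writes small fixture workbooks for round-trip testing.

Cached cell values are trusted as-is: foreign workbook formulas are never
re-evaluated here, their texts are used only to recover dependency edges.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from openpyxl import Workbook, load_workbook

from .compare import Tolerance, compare_grids
from .engines import CellGrid
from .impact import ImpactReport, impact_report
from .layout import GridLayout, RowSpec
from .propagate import ErrorClassification

__all__ = [
    "WorkbookExtract",
    "read_workbook",
    "write_workbook",
    "diff_workbooks",
    "VERSION_TABS",
]

log = logging.getLogger(__name__)

#: Model tabs expected per workbook, keyed by version tag.
VERSION_TABS = {"SN": "Model (SN)", "SC": "Model (SC)", "M": "Model (Matrix)"}

#: Shadow-sheet suffix carrying fixture formula texts (see write_workbook).
FORMULA_TAB_SUFFIX = " ~formulas"

#: Default region: year headers in row 1 from column B, row labels in
#: column A from row 2, data block from B2 to the used extent.
DEFAULT_REGION = {"header_row": 1, "label_col": 1, "first_data_row": 2, "first_data_col": 2}

_A1_RE = re.compile(r"\$?([A-Z]{1,3})\$?([0-9]+)")


@dataclass
class WorkbookExtract:
    """Grids and formula texts per tab, plus provenance."""

    grids: dict[str, CellGrid]
    formulas: dict[str, dict[tuple[str, int], str]]
    provenance: dict = field(default_factory=dict)
    missing_tabs: list[str] = field(default_factory=list)


def read_workbook(
    path: str | Path,
    region_config: Mapping | None = None,
    expected_tabs: Sequence[str] | None = None,
) -> WorkbookExtract:
    """Extract numeric grids and formula strings from a workbook.

    ``region_config`` may override the default header/label positions
    globally or per tab (``{"tabs": {tab_name: {...}}}``).  Missing
    expected tabs degrade to a logged warning, not an error.
    """
    path = Path(path)
    wb_values = load_workbook(path, data_only=True)
    wb_formulas = load_workbook(path, data_only=False)
    region_config = dict(region_config or {})
    per_tab = region_config.pop("tabs", {})

    if expected_tabs is not None:
        tabs = list(expected_tabs)
    else:
        tabs = [t for t in wb_values.sheetnames if not t.endswith(FORMULA_TAB_SUFFIX)]
    missing = [t for t in tabs if t not in wb_values.sheetnames]
    if missing:
        log.warning("workbook %s lacks tabs: %s", path.name, missing)

    grids: dict[str, CellGrid] = {}
    formulas: dict[str, dict[tuple[str, int], str]] = {}
    for tab in tabs:
        if tab in missing:
            continue
        region = {**DEFAULT_REGION, **region_config, **per_tab.get(tab, {})}
        ws_v = wb_values[tab]
        ws_f = wb_formulas[tab]
        hr, lc = region["header_row"], region["label_col"]
        r0, c0 = region["first_data_row"], region["first_data_col"]
        years: list[int] = []
        c = c0
        while True:
            v = ws_v.cell(row=hr, column=c).value
            if v is None:
                break
            years.append(int(v))
            c += 1
        labels: list[str] = []
        r = r0
        while True:
            v = ws_v.cell(row=r, column=lc).value
            if v is None:
                break
            labels.append(str(v))
            r += 1
        n_rows = region.get("n_rows", len(labels))
        n_cols = region.get("n_cols", len(years))
        if n_rows > len(labels) or n_cols > len(years):
            raise ValueError(
                f"tab {tab!r}: configured region ({n_rows}x{n_cols}) exceeds "
                f"sheet extent ({len(labels)}x{len(years)})"
            )
        labels, years = labels[:n_rows], years[:n_cols]
        values = np.zeros((len(labels), len(years)))
        texts: dict[tuple[str, int], str] = {}
        for i, label in enumerate(labels):
            for j, year in enumerate(years):
                cell_v = ws_v.cell(row=r0 + i, column=c0 + j).value
                cell_f = ws_f.cell(row=r0 + i, column=c0 + j).value
                if isinstance(cell_f, str) and cell_f.startswith("="):
                    texts[(label, year)] = cell_f
                if isinstance(cell_v, (int, float)):
                    values[i, j] = float(cell_v)
                elif isinstance(cell_f, (int, float)):
                    values[i, j] = float(cell_f)
        # fixture workbooks carry formula texts in a shadow sheet, since a
        # freshly written file has no cached formula values
        shadow = tab + FORMULA_TAB_SUFFIX
        if shadow in wb_formulas.sheetnames:
            ws_s = wb_formulas[shadow]
            for i, label in enumerate(labels):
                for j, year in enumerate(years):
                    cell_s = ws_s.cell(row=r0 + i, column=c0 + j).value
                    if isinstance(cell_s, str) and cell_s.startswith("="):
                        texts[(label, year)] = cell_s
        layout = GridLayout(
            rows=tuple(RowSpec(l, "unknown") for l in labels), years=tuple(years)
        )
        grids[tab] = CellGrid(layout=layout, values=values)
        formulas[tab] = texts
    return WorkbookExtract(
        grids=grids,
        formulas=formulas,
        provenance={"filename": path.name, "sheets": list(wb_values.sheetnames)},
        missing_tabs=missing,
    )


def write_workbook(
    path: str | Path,
    grids: Mapping[str, CellGrid],
    formulas: Mapping[str, Mapping[tuple[str, int], str]] | None = None,
) -> None:
    """Write grids (and optional formula texts) as a small fixture workbook.

    Numeric values go in the model tabs; formula texts, when given, are
    written to a shadow ``<tab> [formulas]`` sheet, because a workbook
    written programmatically carries no cached formula results and a
    formula cell would otherwise read back as empty.
    """
    wb = Workbook()
    wb.remove(wb.active)
    for tab, grid in grids.items():
        ws = wb.create_sheet(title=tab)
        for j, year in enumerate(grid.layout.years):
            ws.cell(row=1, column=2 + j, value=int(year))
        for i, row in enumerate(grid.layout.rows):
            ws.cell(row=2 + i, column=1, value=row.label)
            for j, year in enumerate(grid.layout.years):
                ws.cell(row=2 + i, column=2 + j, value=float(grid.values[i, j]))
        texts = (formulas or {}).get(tab)
        if texts:
            ws_s = wb.create_sheet(title=tab + FORMULA_TAB_SUFFIX)
            for j, year in enumerate(grid.layout.years):
                ws_s.cell(row=1, column=2 + j, value=int(year))
            for i, row in enumerate(grid.layout.rows):
                ws_s.cell(row=2 + i, column=1, value=row.label)
                for j, year in enumerate(grid.layout.years):
                    key = (row.label, year)
                    if key in texts:
                        ws_s.cell(row=2 + i, column=2 + j, value=texts[key])
    wb.save(Path(path))


def _formula_edges(
    texts: Mapping[tuple[str, int], str], layout: GridLayout
) -> "dict[tuple[str, int], set[tuple[str, int]]]":
    """Dependency edges recovered from A1-style formula texts: cell -> the
    grid cells it references (references outside the grid are dropped)."""
    edges: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for key, text in texts.items():
        deps: set[tuple[str, int]] = set()
        for letters, digits in _A1_RE.findall(text):
            col = 0
            for ch in letters:
                col = col * 26 + (ord(ch) - ord("A") + 1)
            r, c = int(digits) - 2, col - 2  # data block starts at B2
            if 0 <= r < layout.n_rows and 0 <= c < layout.n_years:
                deps.add((layout.rows[r].label, layout.years[c]))
        edges[key] = deps
    return edges


def diff_workbooks(
    errors_path: str | Path,
    corrected_path: str | Path,
    region_config: Mapping | None = None,
    threshold: float = 5.0,
    tol: Tolerance = Tolerance(rel=0.0, abs=1e-6),
) -> dict[str, dict]:
    """Replay the verification analysis on a with-errors/corrected pair.

    For each model version tab present in both workbooks: compare grids,
    classify discrepant cells into original (own formula text differs) vs
    propagated (value wrong, formula identical -- wrong only through its
    inputs), and compute the impact report against the corrected grid as
    gold standard.  Without formula texts the classification degrades to
    counts-only with a warning.
    """
    ex_err = read_workbook(errors_path, region_config, expected_tabs=list(VERSION_TABS.values()))
    ex_cor = read_workbook(corrected_path, region_config, expected_tabs=list(VERSION_TABS.values()))
    out: dict[str, dict] = {}
    for version, tab in VERSION_TABS.items():
        if tab not in ex_err.grids or tab not in ex_cor.grids:
            log.warning("version tab %r absent from one workbook; skipped", tab)
            continue
        g_err, g_cor = ex_err.grids[tab], ex_cor.grids[tab]
        report = compare_grids(g_err, g_cor, tol=tol, pair=(f"{version}-errors", f"{version}-corrected"))
        impact = impact_report(g_err, g_cor, threshold=threshold)

        t_err, t_cor = ex_err.formulas.get(tab, {}), ex_cor.formulas.get(tab, {})
        classification = None
        if t_err or t_cor:
            discrepant = report.addresses()
            originals = frozenset(
                key for key in discrepant if t_err.get(key) != t_cor.get(key)
            )
            propagated = discrepant - originals
            # validate propagation: every propagated cell should be reachable
            # from an original along recovered dependency edges
            edges = _formula_edges(t_err, g_err.layout)
            downstream: dict[tuple[str, int], set] = {}
            for cell, deps in edges.items():
                for d in deps:
                    downstream.setdefault(d, set()).add(cell)
            reached = set(originals)
            frontier = list(originals)
            while frontier:
                cell = frontier.pop()
                for nxt in downstream.get(cell, ()):
                    if nxt not in reached:
                        reached.add(nxt)
                        frontier.append(nxt)
            unexplained = propagated - reached
            if unexplained:
                log.warning(
                    "version %s: %d propagated cells not reachable from an original "
                    "via recovered formula edges", version, len(unexplained)
                )
            classification = ErrorClassification(
                originals=originals,
                propagated=frozenset(propagated),
                undetectable_originals=frozenset(),
                per_operator={},
            )
        else:
            log.warning("version %s: no formula texts; classification is counts-only", version)
        out[version] = {
            "report": report,
            "classification": classification,
            "n_discrepant": len(report),
            "impact": impact,
        }
    return out
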