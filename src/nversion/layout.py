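"""Compact-grid layout: the spreadsheet the verification method operates on.

Every engine projects its computation into the same compact grid -- one row
per health state plus declared aggregate rows, one column per calendar year.
The grid cell is the unit over which discrepancy detection, error counting
and materiality analysis are all defined.

Two addressing modes exist, mirroring the two formula-based model versions:
*named* (``label@Y2013``) and *positional* (``R12C4``, 0-based).  The two
are bijective over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .structure import CareStatus, ModelStructure, Stage

__all__ = [
    "RowSpec",
    "GridLayout",
    "default_layout",
    "default_continuum_mapping",
    "CONTINUUM_STEPS",
]

#: Care-continuum steps, in cascade order.
CONTINUUM_STEPS = (
    "HIV_INFECTED",
    "DIAGNOSED_LINKED",
    "RECEIVING_ART",
    "RETAINED_PRE_ART",
    "RETAINED_ON_ART",
)


@dataclass(frozen=True)
class RowSpec:
    """One grid row: a state row, an aggregate (sum of state rows), or the
    entry row carrying per-year cohort sizes."""

    label: str
    kind: str  # "state" | "aggregate" | "entry"
    members: tuple[str, ...] = ()


@dataclass(frozen=True)
class GridLayout:
    rows: tuple[RowSpec, ...]
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rows]
        if len(set(labels)) != len(labels):
            raise ValueError("row labels must be unique")
        if len(set(self.years)) != len(self.years):
            raise ValueError("year labels must be unique")
        object.__setattr__(self, "_row_index", {r.label: i for i, r in enumerate(self.rows)})
        object.__setattr__(self, "_year_index", {y: j for j, y in enumerate(self.years)})

    # -- sizes -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_cells(self) -> int:
        """Compact-grid cell count (rows x years)."""
        return self.n_rows * self.n_years

    @property
    def state_rows(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rows if r.kind == "state")

    # -- addressing ------------------------------------------------------

    def row_index(self, label: str) -> int:
        return self._row_index[label]

    def year_index(self, year: int) -> int:
        return self._year_index[year]

    def named_address(self, label: str, year: int) -> str:
        if label not in self._row_index or year not in self._year_index:
            raise KeyError((label, year))
        return f"{label}@Y{year}"

    def positional_address(self, label: str, year: int) -> str:
        return f"R{self.row_index(label)}C{self.year_index(year)}"

    def cell_from_positional(self, r: int, c: int) -> tuple[str, int]:
        if not (0 <= r < self.n_rows and 0 <= c < self.n_years):
            raise KeyError((r, c))
        return self.rows[r].label, self.years[c]

    def a1_address(self, label: str, year: int) -> str:
        """Spreadsheet-style rendering for reports (labels in column A,
        years in row 1, data block from B2)."""
        col = self.year_index(year) + 2
        letters = ""
        while col:
            col, rem = divmod(col - 1, 26)
            letters = chr(ord("A") + rem) + letters
        return f"{letters}{self.row_index(label) + 2}"

    def cells(self) -> Iterable[tuple[str, int]]:
        for r in self.rows:
            for y in self.years:
                yield (r.label, y)


def default_continuum_mapping(structure: ModelStructure) -> dict[str, tuple[str, ...]]:
    """Map care-continuum steps to member state ids.

    Defaults: total = all live states; diagnosed/linked = ever engaged in
    care (pre-ART care, on ART, or LTFU after engagement); receiving ART =
    all ART-experienced strata; retained pre-ART = in pre-ART care; retained
    on ART = on ART and still engaged.
    """
    live = [s for s in structure.states if not s.is_dead]
    return {
        "HIV_INFECTED": tuple(s.id for s in live),
        "DIAGNOSED_LINKED": tuple(
            s.id
            for s in live
            if s.care_status in (CareStatus.PRE_ART_CARE, CareStatus.ON_ART, CareStatus.LTFU)
        ),
        "RECEIVING_ART": tuple(s.id for s in live if s.stage is Stage.ON_ART),
        "RETAINED_PRE_ART": tuple(s.id for s in live if s.care_status is CareStatus.PRE_ART_CARE),
        "RETAINED_ON_ART": tuple(s.id for s in live if s.care_status is CareStatus.ON_ART),
    }


def default_layout(structure: ModelStructure, years: Sequence[int]) -> GridLayout:
    """Build the default compact layout for a structure.

    Rows: all state rows in declaration order, then one total per main-state
    group, the five care-continuum rows, alive/dead/grand totals, and the
    entry row.  For the default 48-state baseline over 15 years this yields
    roughly 1,050 cells, on the order of the published compact workbook.
    """
    rows: list[RowSpec] = [RowSpec(s.id, "state") for s in structure.states]
    by_group: dict[str, list[str]] = {}
    for s in structure.states:
        by_group.setdefault(s.main_group or s.id, []).append(s.id)
    for group in structure.main_groups:
        rows.append(RowSpec(f"TOTAL_{group}", "aggregate", tuple(by_group[group])))
    for step, members in default_continuum_mapping(structure).items():
        rows.append(RowSpec(f"CONTINUUM_{step}", "aggregate", members))
    live = tuple(s.id for s in structure.states if not s.is_dead)
    dead = tuple(s.id for s in structure.states if s.is_dead)
    rows.append(RowSpec("TOTAL_ALIVE", "aggregate", live))
    rows.append(RowSpec("TOTAL_DEAD", "aggregate", dead))
    rows.append(RowSpec("TOTAL_ALL", "aggregate", live + dead))
    rows.append(RowSpec("ENTRIES", "entry"))
    return GridLayout(rows=tuple(rows), years=tuple(int(y) for y in years))
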