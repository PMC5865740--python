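"""Error impact: percentage differences, materiality, and continuum deltas.

For each compact-grid cell the impact of unintentional errors is the signed
percentage difference between the model version *with* errors and the
corrected, gold-standard version:

    %difference_c = (n_c,errors - n_c,noerrors) / n_c,noerrors * 100

A cell whose difference exceeds +/-5% (strictly) carries a *material*
error; a nonzero difference at or below the threshold is non-material.
Cells where the gold standard is zero but the errored value is not have an
undefined percentage difference: they are flagged UNDEFINED, excluded from
the percentage tallies, and counted separately (mapping them silently to 0
or infinity would corrupt the tallies).

The same arithmetic applied to step totals along the HIV care continuum
(infected -> diagnosed/linked -> receiving ART -> retained pre-ART /
on ART) gives the policy-relevant impact view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .engines import CellGrid
from .layout import CONTINUUM_STEPS, default_continuum_mapping

__all__ = [
    "NO_ERROR",
    "NON_MATERIAL",
    "MATERIAL",
    "UNDEFINED",
    "MaterialityTally",
    "Histogram",
    "ImpactReport",
    "ContinuumOutcomes",
    "percent_difference",
    "classify_materiality",
    "impact_distribution",
    "impact_report",
    "continuum",
    "continuum_impact",
]

NO_ERROR = "NO_ERROR"
NON_MATERIAL = "NON_MATERIAL"
MATERIAL = "MATERIAL"
UNDEFINED = "UNDEFINED"

ZERO_TOL = 1e-9

#: Default magnitude bins for the error-size distribution (percent).
DEFAULT_BINS = ("0", "(0,5]", "(5,25]", "(25,100]", ">100")


def percent_difference(
    errors_grid: CellGrid, clean_grid: CellGrid, zero_tol: float = ZERO_TOL
) -> tuple[dict[tuple[str, int], float], frozenset[tuple[str, int]]]:
    """Per-cell signed percentage difference of errored vs gold standard.

    Returns ``(pct, undefined)`` where ``pct[(row, year)]`` is the signed
    percent (0.0 where both cells are zero) and ``undefined`` collects the
    zero-clean/nonzero-error cells, which are excluded from ``pct``.
    """
    labels_e = tuple(r.label for r in errors_grid.layout.rows)
    labels_c = tuple(r.label for r in clean_grid.layout.rows)
    if labels_e != labels_c or errors_grid.layout.years != clean_grid.layout.years:
        raise ValueError("grid layouts do not match")
    pct: dict[tuple[str, int], float] = {}
    undefined: set[tuple[str, int]] = set()
    ve, vc = errors_grid.values, clean_grid.values
    for i, label in enumerate(labels_e):
        for j, year in enumerate(errors_grid.layout.years):
            clean = vc[i, j]
            err = ve[i, j]
            if abs(clean) <= zero_tol:
                if abs(err) <= zero_tol:
                    pct[(label, year)] = 0.0
                else:
                    undefined.add((label, year))
            else:
                pct[(label, year)] = (err - clean) / clean * 100.0
    return pct, frozenset(undefined)


@dataclass(frozen=True)
class MaterialityTally:
    """Counts per materiality class; the three classes partition all cells
    with a defined percentage difference."""

    n_no_error: int
    n_non_material: int
    n_material: int
    n_undefined: int = 0

    @property
    def n_cells(self) -> int:
        return self.n_no_error + self.n_non_material + self.n_material + self.n_undefined

    def column_percentages(self) -> dict[str, float]:
        denom = self.n_cells or 1
        return {
            NO_ERROR: 100.0 * self.n_no_error / denom,
            NON_MATERIAL: 100.0 * self.n_non_material / denom,
            MATERIAL: 100.0 * self.n_material / denom,
            UNDEFINED: 100.0 * self.n_undefined / denom,
        }


def classify_materiality(
    pct: Mapping[tuple[str, int], float],
    threshold: float = 5.0,
    zero_tol: float = ZERO_TOL,
    undefined: frozenset[tuple[str, int]] = frozenset(),
) -> tuple[dict[tuple[str, int], str], MaterialityTally]:
    """Flag every cell NO_ERROR / NON_MATERIAL / MATERIAL.

    The boundary follows the materiality convention: a difference of
    exactly the threshold is non-material; strictly greater is material.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flags: dict[tuple[str, int], str] = {}
    counts = {NO_ERROR: 0, NON_MATERIAL: 0, MATERIAL: 0}
    for key, value in pct.items():
        mag = abs(value)
        if mag <= zero_tol:
            flag = NO_ERROR
        elif mag <= threshold:
            flag = NON_MATERIAL
        else:
            flag = MATERIAL
        flags[key] = flag
        counts[flag] += 1
    for key in undefined:
        flags[key] = UNDEFINED
    tally = MaterialityTally(
        n_no_error=counts[NO_ERROR],
        n_non_material=counts[NON_MATERIAL],
        n_material=counts[MATERIAL],
        n_undefined=len(undefined),
    )
    return flags, tally


@dataclass(frozen=True)
class Histogram:
    bin_labels: tuple[str, ...]
    counts: tuple[int, ...]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.bin_labels, self.counts))

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def impact_distribution(
    pct: Mapping[tuple[str, int], float],
    bins: Sequence[float] | None = None,
    zero_tol: float = ZERO_TOL,
) -> Histogram:
    """Distribution of per-cell error sizes.

    With ``bins=None`` the default magnitude bins are used: an exact-zero
    spike (no error) plus ``(0,5]``, ``(5,25]``, ``(25,100]`` and ``>100``
    percent.  Passing numeric ``bins`` edges produces a signed histogram
    over those edges, with the zero spike always reported as its own bin.
    """
    values = np.asarray(list(pct.values()), dtype=float)
    if values.size == 0:
        return Histogram(bin_labels=(), counts=())
    zero_mask = np.abs(values) <= zero_tol
    nonzero = values[~zero_mask]
    if bins is None:
        mags = np.abs(nonzero)
        counts = (
            int(zero_mask.sum()),
            int(((mags > 0) & (mags <= 5)).sum()),
            int(((mags > 5) & (mags <= 25)).sum()),
            int(((mags > 25) & (mags <= 100)).sum()),
            int((mags > 100).sum()),
        )
        return Histogram(bin_labels=DEFAULT_BINS, counts=counts)
    edges = np.asarray(bins, dtype=float)
    hist, _ = np.histogram(nonzero, bins=edges)
    labels = ["0"] + [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
    return Histogram(
        bin_labels=tuple(labels), counts=(int(zero_mask.sum()), *(int(h) for h in hist))
    )


@dataclass(frozen=True)
class ImpactReport:
    percent_diff: Mapping[tuple[str, int], float]
    undefined: frozenset[tuple[str, int]]
    flags: Mapping[tuple[str, int], str]
    threshold: float
    tally: MaterialityTally
    distribution: Histogram
    doubling_count: int  # material cells whose |%diff| exceeds 100


def impact_report(
    errors_grid: CellGrid,
    clean_grid: CellGrid,
    threshold: float = 5.0,
    bins: Sequence[float] | None = None,
) -> ImpactReport:
    """Full per-cell impact analysis of an errored grid vs its gold standard."""
    pct, undefined = percent_difference(errors_grid, clean_grid)
    flags, tally = classify_materiality(pct, threshold=threshold, undefined=undefined)
    dist = impact_distribution(pct, bins=bins)
    doubling = sum(1 for v in pct.values() if abs(v) > 100.0)
    return ImpactReport(
        percent_diff=pct,
        undefined=undefined,
        flags=flags,
        threshold=threshold,
        tally=tally,
        distribution=dist,
        doubling_count=doubling,
    )


# ---------------------------------------------------------------------------
# care continuum


@dataclass(frozen=True)
class ContinuumOutcomes:
    """Person-counts at one calendar year for the five cascade steps."""

    hiv_infected: float
    diagnosed_linked: float
    receiving_art: float
    retained_pre_art: float
    retained_on_art: float

    def as_dict(self) -> dict[str, float]:
        return {
            "HIV_INFECTED": self.hiv_infected,
            "DIAGNOSED_LINKED": self.diagnosed_linked,
            "RECEIVING_ART": self.receiving_art,
            "RETAINED_PRE_ART": self.retained_pre_art,
            "RETAINED_ON_ART": self.retained_on_art,
        }


def continuum(
    grid: CellGrid,
    mapping: Mapping[str, Sequence[str]] | None = None,
    year: int | None = None,
) -> ContinuumOutcomes:
    """Sum state rows into cascade steps at one year (default: final year).

    ``mapping`` maps each step name to its member state row labels; every
    live (non-dead) state row of the grid must be covered by the
    HIV_INFECTED step, otherwise the mapping is rejected.
    """
    layout = grid.layout
    if year is None:
        year = layout.years[-1]
    if year not in layout.years:
        raise ValueError(f"year {year} outside the grid horizon")
    if mapping is None:
        # derive from the layout's continuum aggregate rows when present
        rows = {r.label: r for r in layout.rows}
        mapping = {}
        for step in CONTINUUM_STEPS:
            row = rows.get(f"CONTINUUM_{step}")
            if row is None:
                raise ValueError(
                    f"grid lacks a CONTINUUM_{step} row; pass an explicit mapping"
                )
            mapping = {**mapping, step: row.members}
    missing = [s for s in CONTINUUM_STEPS if s not in mapping]
    if missing:
        raise ValueError(f"mapping lacks steps {missing}")
    state_rows = set(grid.layout.state_rows)
    if state_rows:
        uncovered = state_rows - set(mapping["HIV_INFECTED"])
        # dead states are legitimately outside the continuum
        uncovered = {s for s in uncovered if not s.startswith("DEAD")}
        if uncovered:
            raise ValueError(f"live states not covered by mapping: {sorted(uncovered)}")

    def step_total(step: str) -> float:
        return float(sum(grid.value(label, year) for label in mapping[step]))

    return ContinuumOutcomes(
        hiv_infected=step_total("HIV_INFECTED"),
        diagnosed_linked=step_total("DIAGNOSED_LINKED"),
        receiving_art=step_total("RECEIVING_ART"),
        retained_pre_art=step_total("RETAINED_PRE_ART"),
        retained_on_art=step_total("RETAINED_ON_ART"),
    )


def continuum_impact(
    errors_grid: CellGrid,
    clean_grid: CellGrid,
    mapping: Mapping[str, Sequence[str]] | None = None,
    year: int | None = None,
    zero_tol: float = ZERO_TOL,
) -> dict[str, float]:
    """Percentage difference of each cascade-step total (errored vs clean).

    Steps whose clean total is zero while the errored one is not are
    reported as ``nan`` (undefined), mirroring the per-cell convention.
    """
    err = continuum(errors_grid, mapping, year).as_dict()
    ref = continuum(clean_grid, mapping, year).as_dict()
    out: dict[str, float] = {}
    for step in err:
        if abs(ref[step]) <= zero_tol:
            out[step] = 0.0 if abs(err[step]) <= zero_tol else math.nan
        else:
            out[step] = (err[step] - ref[step]) / ref[step] * 100.0
    return out
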