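"""Cross-version discrepancy detection and verification completion.

An unintentional implementation error is detected when the projected number
in a compact-grid cell differs between two model versions.  With exact
spreadsheet recalculation the difference of concordant cells is literally
zero; independent floating-point engines instead agree to within a
tolerance far below any materially relevant scale, so a cell is flagged
only when ``|a - b| > max(abs_tol, rel_tol * max(|a|, |b|))``.

Verification of a revision is complete when all three pairwise reports
(SN-SC, SN-M, SC-M) are empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engines import CellGrid

__all__ = ["Tolerance", "Discrepancy", "DiscrepancyReport", "compare_grids", "verification_complete"]

#: Canonical version tags: Single Name, Single Cell, Matrix.
VERSIONS = ("SN", "SC", "M")


@dataclass(frozen=True)
class Tolerance:
    rel: float = 1e-9
    abs: float = 1e-6


@dataclass(frozen=True)
class Discrepancy:
    address: tuple[str, int]  # (row label, year)
    value_a: float
    value_b: float

    @property
    def difference(self) -> float:
        return self.value_a - self.value_b


@dataclass
class DiscrepancyReport:
    """All cells of one version pair differing beyond tolerance, sorted by
    (year, row index) for stable diffs."""

    pair: tuple[str, str]
    discrepancies: list[Discrepancy]
    tolerance: Tolerance

    @property
    def is_empty(self) -> bool:
        return not self.discrepancies

    def addresses(self) -> frozenset[tuple[str, int]]:
        return frozenset(d.address for d in self.discrepancies)

    def __len__(self) -> int:
        return len(self.discrepancies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "row": d.address[0],
                    "year": d.address[1],
                    "value_a": d.value_a,
                    "value_b": d.value_b,
                    "difference": d.difference,
                }
                for d in self.discrepancies
            ],
            columns=["row", "year", "value_a", "value_b", "difference"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_grids(
    a: CellGrid,
    b: CellGrid,
    tol: Tolerance = Tolerance(),
    pair: tuple[str, str] = ("A", "B"),
) -> DiscrepancyReport:
    """Cell-wise comparison of two grids sharing a layout.

    A layout mismatch is a structural error worth surfacing, not something
    to align silently, so it raises ``ValueError``.
    """
    labels_a = tuple(r.label for r in a.layout.rows)
    labels_b = tuple(r.label for r in b.layout.rows)
    if labels_a != labels_b or a.layout.years != b.layout.years:
        raise ValueError("grid layouts do not match")

    va, vb = a.values, b.values
    thresh = np.maximum(tol.abs, tol.rel * np.maximum(np.abs(va), np.abs(vb)))
    mask = np.abs(va - vb) > thresh

    discrepancies: list[Discrepancy] = []
    rows = labels_a
    for j, year in enumerate(a.layout.years):
        for i in np.where(mask[:, j])[0]:
            discrepancies.append(
                Discrepancy(address=(rows[i], year), value_a=float(va[i, j]), value_b=float(vb[i, j]))
            )
    return DiscrepancyReport(pair=tuple(pair), discrepancies=discrepancies, tolerance=tol)


def verification_complete(reports: Sequence[DiscrepancyReport]) -> bool:
    """True iff all three pairwise reports over the three versions are empty.

    Raises ``ValueError`` unless the reports cover exactly the three
    distinct unordered version pairs of one revision.
    """
    pairs = {frozenset(r.pair) for r in reports}
    versions = set().union(*pairs) if pairs else set()
    if len(reports) != 3 or len(pairs) != 3 or len(versions) != 3 or any(len(p) != 2 for p in pairs):
        raise ValueError("verification requires the three pairwise reports over three versions")
    return all(r.is_empty for r in reports)
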