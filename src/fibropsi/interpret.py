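"""Variable interpretation: GA occurrence tallies, PC1-loadings /
mean-difference peak discovery, and [M+H]+ annotation against a local
compound table.

The tally pools the m/z sets selected by GA runs (across datasets and
triplicate executions) and keeps variables that occur at least twice.
The loadings-difference analysis computes d = mean(CG) − mean(FG) over
the m/z axis and selects negative peaks of d — greater intensity in
cases — that coincide with local extrema of the PC1 loading vector.
Annotation matches selected m/z against protonated molecular ions,
observed m/z ≈ neutral monoisotopic mass + 1.00728 Da, within a mass
tolerance (default ± 0.1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, find_peaks

from .io import CASE, CONTROL, SpectralMatrix
from .reduce import ReductionResult

__all__ = [
    "VariableTally",
    "LoadingsDiffReport",
    "CompoundEntry",
    "AnnotationHit",
    "PROTON_MASS",
    "tally_ga_variables",
    "loadings_difference",
    "annotate_mz",
    "load_compound_table",
]

PROTON_MASS = 1.00728  # Da, charge-corrected proton for [M+H]+


@dataclass
class VariableTally:
    counts: dict[int, int]
    threshold: int
    retained: list[int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()),
            columns=["mz", "count"],
        ).assign(retained=lambda d: d["count"] >= self.threshold)


@dataclass
class LoadingsDiffReport:
    difference: np.ndarray   # mean(CG) - mean(FG) per m/z
    mz_axis: np.ndarray
    pc1_loading: np.ndarray
    selected_mz: list[int]
    depth_frac: float


@dataclass
class CompoundEntry:
    name: str
    neutral_mass: float  # monoisotopic, Da
    compound_class: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name}: neutral mass must be positive")


@dataclass
class AnnotationHit:
    query_mz: float
    name: str
    neutral_mass: float
    mass_error: float
    compound_class: str = ""


def tally_ga_variables(
    runs: Sequence[ReductionResult], threshold: int = 2
) -> VariableTally:
    """Count m/z occurrences over GA runs; keep those occurring at least
    ``threshold`` times (a variable appearing several times within one
    run still counts once for that run)."""
    if not runs:
        raise ValueError("no GA runs to tally")
    for r in runs:
        if r.method != "GA":
            raise ValueError("tally_ga_variables expects GA reduction results")
    counter: Counter[int] = Counter()
    for r in runs:
        counter.update(set(r.selected_mz or []))
    retained = sorted(v for v, c in counter.items() if c >= threshold)
    return VariableTally(counts=dict(sorted(counter.items())), threshold=threshold, retained=retained)


def loadings_difference(
    matrix: SpectralMatrix,
    pca: ReductionResult,
    depth_frac: float = 0.2,
    coincidence_window: int = 1,
) -> LoadingsDiffReport:
    """Select case-elevated m/z from the class-mean difference and PC1.

    Local minima of d = mean(CG) − mean(FG) with depth at least
    ``depth_frac × max|d|`` are candidate case markers (negative peaks of
    d mean greater intensity in FG).  A candidate is retained only if the
    PC1 loading vector has a local extremum (of either sign) within
    ``± coincidence_window`` m/z of it.
    """
    if pca.method != "PCA" or pca.loadings is None:
        raise ValueError("loadings_difference needs a fitted PCA result")
    labels = matrix.labels.astype(str)
    if CONTROL not in labels or CASE not in labels:
        raise ValueError("both classes must be present")
    d = matrix.X[labels == CONTROL].mean(axis=0) - matrix.X[labels == CASE].mean(axis=0)
    l1 = pca.loadings[:, 0]
    max_abs = np.abs(d).max()
    selected: list[int] = []
    if max_abs > 0:
        # negative peaks of d: peaks of -d above the depth threshold
        minima, _ = find_peaks(-d, height=depth_frac * max_abs)
        extrema = np.union1d(
            argrelextrema(l1, np.greater)[0], argrelextrema(l1, np.less)[0]
        )
        for i in minima:
            if d[i] < 0 and extrema.size and np.min(np.abs(extrema - i)) <= coincidence_window:
                selected.append(int(matrix.mz_axis[i]))
    return LoadingsDiffReport(
        difference=d,
        mz_axis=matrix.mz_axis,
        pc1_loading=l1,
        selected_mz=sorted(selected),
        depth_frac=depth_frac,
    )


def annotate_mz(
    variables: Iterable[float],
    table: Sequence[CompoundEntry],
    tolerance: float = 0.1,
    proton_mass: float = PROTON_MASS,
) -> list[AnnotationHit]:
    """Match query m/z against [M+H]+ ions of a compound table.

    A hit requires |query − (neutral mass + proton mass)| ≤ tolerance;
    hits are returned sorted by absolute mass error.  An empty table
    yields an empty hit list.
    """
    hits: list[AnnotationHit] = []
    for v in variables:
        for entry in table:
            err = v - (entry.neutral_mass + proton_mass)
            if abs(err) <= tolerance:
                hits.append(
                    AnnotationHit(
                        query_mz=float(v),
                        name=entry.name,
                        neutral_mass=entry.neutral_mass,
                        mass_error=float(err),
                        compound_class=entry.compound_class,
                    )
                )
    return sorted(hits, key=lambda h: abs(h.mass_error))


def load_compound_table(path: str | Path) -> list[CompoundEntry]:
    """Read a compound table CSV: name, neutral_monoisotopic_mass, class."""
    df = pd.read_csv(path)
    required = {"name", "neutral_monoisotopic_mass"}
    if not required <= set(df.columns):
        raise ValueError(f"compound table needs columns {sorted(required)}")
    return [
        CompoundEntry(
            name=str(row["name"]),
            neutral_mass=float(row["neutral_monoisotopic_mass"]),
            compound_class=str(row.get("class", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def annotation_to_dataframe(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mz": h.query_mz,
                "name": h.name,
                "mass_error": h.mass_error,
                "class": h.compound_class,
            }
            for h in hits
        ],
        columns=["mz", "name", "mass_error", "class"],
    )
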