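"""Spectral and clinical data containers, file I/O, binning, replicate
averaging and symptom-level dataset assembly.

The central in-memory object is :class:`SpectralMatrix`, a samples ×
nominal-m/z intensity matrix carrying group labels (``CG`` control,
``FG`` fibromyalgia) and a free-text provenance log that every pipeline
stage appends to.  Spectra enter either as per-spectrum centroid peak
lists (``peaklist-csv``, optionally mzML) or as an already-binned matrix
CSV; centroids are binned to unit (nominal) mass because the working
resolution of the ion-trap data is 1 m/z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumRecord",
    "SpectralMatrix",
    "ClinicalRecord",
    "SCALE_RANGES",
    "read_spectra",
    "write_peaklist",
    "bin_to_nominal",
    "average_replicates",
    "stratify_level",
    "assemble_dataset",
    "read_clinical",
    "write_clinical",
    "read_matrix_csv",
    "write_matrix_csv",
]

CONTROL, CASE = "CG", "FG"

#: Legal score range per clinical scale (inclusive).
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "VAS": (0.0, 100.0),   # pain visual-analogue scale, mm
    "FIQ": (0.0, 100.0),   # fibromyalgia impact questionnaire
    "HAM": (0.0, 56.0),    # Hamilton anxiety rating scale
    "TAMPA": (17.0, 68.0), # Tampa kinesiophobia scale
    "QL": (0.0, 100.0),    # SF-36 quality of life
    "CAT": (0.0, 60.0),    # pain catastrophizing scale
}

SYMPTOMS = tuple(SCALE_RANGES)


@dataclass
class SpectrumRecord:
    """A single acquired spectrum: ascending centroid m/z and intensities."""

    sample_id: str
    replicate_id: str
    mz_values: np.ndarray
    intensities: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError(
                f"spectrum {self.sample_id}/{self.replicate_id}: m/z and "
                f"intensity lengths differ ({self.mz_values.size} vs "
                f"{self.intensities.size})"
            )
        if self.mz_values.size and np.any(np.diff(self.mz_values) <= 0):
            raise ValueError(
                f"spectrum {self.sample_id}/{self.replicate_id}: m/z values "
                "must be strictly ascending"
            )
        if np.any(self.intensities < 0):
            raise ValueError(
                f"spectrum {self.sample_id}/{self.replicate_id}: negative "
                "intensity encountered"
            )


@dataclass
class SpectralMatrix:
    """Samples × nominal-m/z intensity matrix with labels and provenance.

    ``X[i, j]`` is the intensity of sample (or replicate) ``i`` at the
    integer m/z ``mz_axis[j]``.  ``replicate_ids`` is present while rows
    are individual replicates and ``None`` once replicates have been
    averaged into one row per sample.
    """

    X: np.ndarray
    mz_axis: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    replicate_ids: list[str] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples × variables)")
        n, p = self.X.shape
        if self.mz_axis.size != p:
            raise ValueError(f"mz_axis length {self.mz_axis.size} != {p} columns")
        if len(self.sample_ids) != n or self.labels.size != n:
            raise ValueError("sample_ids/labels length mismatch with X rows")
        if self.mz_axis.size and np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly ascending")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing entries")
        if len(set(self.labels.tolist())) > 2:
            raise ValueError("labels take more than two values")

    # -- convenience -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def select_rows(self, idx: Sequence[int], note: str | None = None) -> "SpectralMatrix":
        idx = list(idx)
        out = replace(
            self,
            X=self.X[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            replicate_ids=(
                [self.replicate_ids[i] for i in idx] if self.replicate_ids else None
            ),
            provenance=list(self.provenance),
        )
        if note:
            out.log(note)
        return out

    def select_columns(self, idx: Sequence[int], note: str | None = None) -> "SpectralMatrix":
        idx = list(idx)
        out = replace(
            self,
            X=self.X[:, idx],
            mz_axis=self.mz_axis[idx],
            provenance=list(self.provenance),
        )
        if note:
            out.log(note)
        return out


@dataclass
class ClinicalRecord:
    """Per-patient group label and symptom scores (missing scores = None)."""

    sample_id: str
    group: str
    scores: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (CONTROL, CASE):
            raise ValueError(f"group must be CG or FG, got {self.group!r}")
        for symptom, score in self.scores.items():
            if symptom not in SCALE_RANGES:
                raise ValueError(f"unknown symptom scale {symptom!r}")
            if score is None or (isinstance(score, float) and np.isnan(score)):
                self.scores[symptom] = None
                continue
            lo, hi = SCALE_RANGES[symptom]
            if not lo <= score <= hi:
                raise ValueError(
                    f"{self.sample_id}: {symptom} score {score} outside "
                    f"[{lo}, {hi}]"
                )


# ---------------------------------------------------------------------------
# reading and writing spectra
# ---------------------------------------------------------------------------

def _parse_mz_header(columns: Iterable[str]) -> np.ndarray:
    mz = []
    for c in columns:
        token = c[3:] if c.startswith("mz_") else c
        mz.append(int(token))
    return np.asarray(mz, dtype=int)


def read_spectra(path: str | Path, format: str = "matrix-csv") -> list[SpectrumRecord]:
    """Read spectra from ``matrix-csv``, ``peaklist-csv`` or ``mzml`` files.

    ``matrix-csv`` holds one row per sample/replicate with columns
    ``sample_id, replicate_id, label, <mz ints...>``.  ``peaklist-csv``
    holds one ``mz,intensity`` pair per line for a single spectrum (rows
    are sorted ascending on read).  ``mzml`` reads every spectrum of an
    mzML file through pyteomics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix-csv":
        df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str})
        meta_cols = [c for c in ("sample_id", "replicate_id", "label") if c in df.columns]
        mz = _parse_mz_header([c for c in df.columns if c not in meta_cols])
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError(f"{path}: m/z columns are not strictly ascending")
        records = []
        for i, row in df.iterrows():
            intens = row.drop(meta_cols).to_numpy(dtype=float)
            if np.any(intens < 0):
                raise ValueError(f"{path}: negative intensity in row {i}")
            records.append(
                SpectrumRecord(
                    sample_id=str(row.get("sample_id", f"s{i}")),
                    replicate_id=str(row.get("replicate_id", "r1")),
                    mz_values=mz.astype(float),
                    intensities=intens,
                    label=row.get("label"),
                )
            )
        return records
    if format == "peaklist-csv":
        df = pd.read_csv(path)
        if not {"mz", "intensity"} <= set(df.columns):
            raise ValueError(f"{path}: peaklist-csv needs 'mz,intensity' columns")
        if (df["intensity"] < 0).any():
            bad = int(df.index[df["intensity"] < 0][0])
            raise ValueError(f"{path}: negative intensity in row {bad}")
        df = df.sort_values("mz", kind="stable")
        return [
            SpectrumRecord(
                sample_id=path.stem,
                replicate_id="r1",
                mz_values=df["mz"].to_numpy(float),
                intensities=df["intensity"].to_numpy(float),
            )
        ]
    if format == "mzml":
        from pyteomics import mzml as _mzml

        records = []
        with _mzml.read(str(path)) as reader:
            for k, spec in enumerate(reader):
                records.append(
                    SpectrumRecord(
                        sample_id=path.stem,
                        replicate_id=str(spec.get("id", f"scan{k}")),
                        mz_values=np.asarray(spec["m/z array"], float),
                        intensities=np.asarray(spec["intensity array"], float),
                    )
                )
        return records
    raise ValueError(f"unknown spectra format {format!r}")


def write_peaklist(record: SpectrumRecord, path: str | Path) -> None:
    pd.DataFrame({"mz": record.mz_values, "intensity": record.intensities}).to_csv(
        path, index=False
    )


def bin_to_nominal(record: SpectrumRecord, mz_min: int, mz_max: int) -> np.ndarray:
    """Sum centroid intensities into unit-mass bins over ``[mz_min, mz_max]``.

    Bin ``b`` collects every centroid with ``round(mz) == b``; total
    intensity is conserved for in-range centroids, out-of-range centroids
    are dropped with a warning.
    """
    if mz_min >= mz_max:
        raise ValueError(f"mz_min ({mz_min}) must be < mz_max ({mz_max})")
    grid = np.zeros(mz_max - mz_min + 1)
    if record.mz_values.size == 0:
        return grid
    bins = np.rint(record.mz_values).astype(int)
    in_range = (bins >= mz_min) & (bins <= mz_max)
    if not in_range.all():
        warnings.warn(
            f"spectrum {record.sample_id}/{record.replicate_id}: dropped "
            f"{int((~in_range).sum())} centroid(s) outside [{mz_min}, {mz_max}]"
        )
    np.add.at(grid, bins[in_range] - mz_min, record.intensities[in_range])
    return grid


def average_replicates(
    records: Sequence[SpectrumRecord] | SpectralMatrix,
    mz_min: int | None = None,
    mz_max: int | None = None,
) -> SpectralMatrix:
    """Average replicate spectra into one row per sample.

    Accepts either raw :class:`SpectrumRecord` lists (binned to the
    ``[mz_min, mz_max]`` nominal grid first) or a replicate-level
    :class:`SpectralMatrix`.  Rows are ordered by first appearance of the
    sample id; samples without any replicate are excluded with a warning.
    """
    if isinstance(records, SpectralMatrix):
        matrix = records
        order: list[str] = []
        for sid in matrix.sample_ids:
            if sid not in order:
                order.append(sid)
        rows, labels = [], []
        ids = np.asarray(matrix.sample_ids, dtype=object)
        for sid in order:
            mask = ids == sid
            rows.append(matrix.X[mask].mean(axis=0))
            labels.append(matrix.labels[mask][0])
        out = SpectralMatrix(
            X=np.vstack(rows),
            mz_axis=matrix.mz_axis,
            sample_ids=order,
            labels=np.asarray(labels, dtype=object),
            replicate_ids=None,
            provenance=list(matrix.provenance),
        )
        out.log(f"averaged replicates: {matrix.n_samples} spectra -> {len(order)} samples")
        return out

    if mz_min is None or mz_max is None:
        raise ValueError("mz_min/mz_max required when averaging raw records")
    order = []
    grouped: dict[str, list[np.ndarray]] = {}
    label_of: dict[str, str | None] = {}
    for rec in records:
        if rec.sample_id not in grouped:
            order.append(rec.sample_id)
            grouped[rec.sample_id] = []
            label_of[rec.sample_id] = rec.label
        grouped[rec.sample_id].append(bin_to_nominal(rec, mz_min, mz_max))
    kept = [sid for sid in order if grouped[sid]]
    if len(kept) < len(order):
        warnings.warn("samples without replicates were excluded")
    X = np.vstack([np.mean(grouped[sid], axis=0) for sid in kept])
    out = SpectralMatrix(
        X=X,
        mz_axis=np.arange(mz_min, mz_max + 1),
        sample_ids=kept,
        labels=np.asarray([label_of[s] for s in kept], dtype=object),
        replicate_ids=None,
    )
    out.log(
        f"binned to nominal mass [{mz_min}, {mz_max}] and averaged replicates "
        f"({len(records)} spectra -> {len(kept)} samples)"
    )
    return out


# ---------------------------------------------------------------------------
# clinical stratification
# ---------------------------------------------------------------------------

def stratify_level(symptom: str, score: float | None) -> str:
    """Map a symptom score to its intensity level.

    Cutoffs: HAM ≤7 none / 8–14 mild / 15–23 moderate / ≥24 severe;
    TAMPA 17–34 mild / 35–50 moderate / 51–68 severe; FIQ <39 mild /
    39–59 moderate / >59 severe; VAS(mm) 0–4 none / 5–44 mild / 45–74
    moderate / ≥75 severe; QL 0–25 low / 26–50 regular / 51–75 good /
    76–100 excellent; CAT 0–20 mild / 21–40 moderate / 41–60 high.
    Missing scores map to ``"missing"``.
    """
    if symptom not in SCALE_RANGES:
        raise ValueError(f"unknown symptom scale {symptom!r}")
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "missing"
    lo, hi = SCALE_RANGES[symptom]
    if not lo <= score <= hi:
        raise ValueError(f"{symptom} score {score} outside [{lo}, {hi}]")
    if symptom == "HAM":
        return "none" if score <= 7 else "mild" if score <= 14 else (
            "moderate" if score <= 23 else "severe")
    if symptom == "TAMPA":
        return "mild" if score <= 34 else "moderate" if score <= 50 else "severe"
    if symptom == "FIQ":
        return "mild" if score < 39 else "moderate" if score <= 59 else "severe"
    if symptom == "VAS":
        return "none" if score < 5 else "mild" if score < 45 else (
            "moderate" if score < 75 else "severe")
    if symptom == "QL":
        return "low" if score <= 25 else "regular" if score <= 50 else (
            "good" if score <= 75 else "excellent")
    # CAT
    return "mild" if score <= 20 else "moderate" if score <= 40 else "high"


def assemble_dataset(
    matrix: SpectralMatrix,
    clinical: Sequence[ClinicalRecord],
    symptom: str,
    levels: Iterable[str],
    filter_controls: bool = False,
    min_class_size: int = 4,
) -> SpectralMatrix:
    """Select the case/control dataset for one symptom at given levels.

    Samples missing the symptom score are dropped from both arms.  The
    level filter applies to FG samples (controls are retained regardless
    of their level unless ``filter_controls``).  Refuses to assemble a
    dataset where either class falls below ``min_class_size`` — grids on
    such reduced datasets are not feasible.
    """
    if symptom not in SCALE_RANGES:
        raise ValueError(f"unknown symptom scale {symptom!r}")
    levels = set(levels)
    by_id = {c.sample_id: c for c in clinical}
    keep: list[int] = []
    for i, sid in enumerate(matrix.sample_ids):
        rec = by_id.get(sid)
        if rec is None:
            continue
        level = stratify_level(symptom, rec.scores.get(symptom))
        if level == "missing":
            continue
        if rec.group == CASE or filter_controls:
            if level not in levels:
                continue
        keep.append(i)
    if not keep:
        raise ValueError(f"empty selection for {symptom} levels {sorted(levels)}")
    out = matrix.select_rows(keep)
    counts = out.class_counts()
    n_cg, n_fg = counts.get(CONTROL, 0), counts.get(CASE, 0)
    if min(n_cg, n_fg) < min_class_size:
        raise ValueError(
            f"dataset {symptom}/{sorted(levels)} has too few samples in a "
            f"class (CG={n_cg}, FG={n_fg}, minimum {min_class_size}); "
            "classification on such a reduced dataset is not feasible"
        )
    out.log(
        f"assembled dataset symptom={symptom} levels={sorted(levels)} "
        f"(CG={n_cg}, FG={n_fg})"
    )
    return out


# ---------------------------------------------------------------------------
# matrix / clinical CSV round-trip
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: SpectralMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.X, columns=[f"mz_{m}" for m in matrix.mz_axis])
    df.insert(0, "label", matrix.labels.astype(str))
    df.insert(
        0,
        "replicate_id",
        matrix.replicate_ids if matrix.replicate_ids else ["r1"] * matrix.n_samples,
    )
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> SpectralMatrix:
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str})
    mz = _parse_mz_header([c for c in df.columns if c not in ("sample_id", "replicate_id", "label")])
    X = df.drop(columns=[c for c in ("sample_id", "replicate_id", "label") if c in df]).to_numpy(float)
    return SpectralMatrix(
        X=X,
        mz_axis=mz,
        sample_ids=df["sample_id"].tolist(),
        labels=df["label"].to_numpy(object) if "label" in df else np.asarray([None] * len(df), object),
        replicate_ids=df["replicate_id"].tolist() if "replicate_id" in df else None,
        provenance=[f"read from {path}"],
    )


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"sample_id": rec.sample_id, "group": rec.group}
        for s in SYMPTOMS:
            row[s] = rec.scores.get(s)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    records = []
    for _, row in df.iterrows():
        scores = {
            s: (None if pd.isna(row[s]) else float(row[s]))
            for s in SYMPTOMS
            if s in row
        }
        records.append(ClinicalRecord(str(row["sample_id"]), str(row["group"]), scores))
    return records
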