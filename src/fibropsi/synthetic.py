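"""Synthetic case/control PSI-MS cohort generator with known ground truth.

Emulates unit-resolution positive-mode plasma spectra over m/z 0–900:
a smooth polynomial baseline drift, a common set of plasma peaks whose
heights vary between samples, case-elevated peaks at chosen m/z (the
planted discriminative signal), heteroscedastic shot-like noise,
triplicate acquisition, and per-patient symptom scores drawn from
class-conditional truncated normals so that cases concentrate in the
clinically relevant intensity levels.

Every quantity the downstream pipeline is supposed to recover —
planted m/z, true labels, true baselines, the score table — is returned
in a :class:`SyntheticTruth` object so tests can check recovery against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CASE, CONTROL, SCALE_RANGES, ClinicalRecord, SpectralMatrix, SpectrumRecord

__all__ = ["CohortConfig", "SyntheticTruth", "generate_spectrum", "generate_cohort", "write_cohort"]

#: Shared plasma peak template: (m/z, mean height) for both classes.
DEFAULT_SHARED_PEAKS: tuple[tuple[int, float], ...] = (
    (104, 400.0), (118, 250.0), (132, 300.0), (175, 220.0), (203, 180.0),
    (246, 350.0), (301, 260.0), (311, 200.0), (325, 240.0), (338, 210.0),
    (496, 500.0), (520, 450.0), (579, 300.0), (703, 150.0), (760, 220.0),
)

#: Case-elevated peaks: (m/z, mean height increment for FG samples).
DEFAULT_CASE_PEAKS: tuple[tuple[int, float], ...] = ((301, 80.0), (579, 150.0))

#: Control-arm score mean, within-class SD, and default FG mean shift per
#: scale, placing typical cases at the moderate level of each instrument.
SCORE_MODEL: dict[str, tuple[float, float, float]] = {
    #        cg_mean  sd    fg_shift
    "VAS":   (20.0,  12.0,  38.0),   # FG mean 58 mm -> moderate pain
    "FIQ":   (18.0,  10.0,  32.0),   # FG mean 50 -> moderate impact
    "HAM":   (5.0,    3.0,  14.0),   # FG mean 19 -> moderate anxiety
    "TAMPA": (25.0,   5.0,  17.0),   # FG mean 42 -> moderate kinesiophobia
    "QL":    (78.0,  10.0, -40.0),   # FG mean 38 -> regular quality of life
    "CAT":   (10.0,   6.0,  20.0),   # FG mean 30 -> moderate catastrophizing
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the clinical cohort the pipeline targets: 78 controls
    and 83 fibromyalgia cases, unit-resolution spectra over m/z 0–900,
    triplicate acquisition, and case-elevated peaks at m/z 301 and 579.
    """

    n_control: int = 78
    n_case: int = 83
    mz_min: int = 0
    mz_max: int = 900
    shared_peaks: Sequence[tuple[int, float]] = DEFAULT_SHARED_PEAKS
    case_peaks: Sequence[tuple[int, float]] = DEFAULT_CASE_PEAKS
    baseline_coeffs: Sequence[float] = (30.0, 0.08, -9e-5)  # ascending powers
    noise_sd: float = 0.05
    n_replicates: int = 3
    peak_height_cv: float = 0.10
    peak_width: float = 0.0
    score_effect: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("class sizes must be non-negative")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for mz, _ in list(self.shared_peaks) + list(self.case_peaks):
            if not self.mz_min <= mz <= self.mz_max:
                raise ValueError(f"peak m/z {mz} outside [{self.mz_min}, {self.mz_max}]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for tests and diagnostics."""

    planted_case_mz: set[int]
    true_labels: dict[str, str]
    true_baselines: np.ndarray  # one row per generated spectrum
    score_table: pd.DataFrame
    config: CohortConfig


def _baseline(coeffs: Sequence[float], grid: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(grid.astype(float), np.asarray(coeffs, float))


def _peak_profile(grid: np.ndarray, mz: float, height: float, width: float) -> np.ndarray:
    out = np.zeros_like(grid, dtype=float)
    if width <= 0:
        out[int(round(mz)) - int(grid[0])] = height
        return out
    kernel = np.exp(-0.5 * ((grid - mz) / width) ** 2)
    return height * kernel / kernel.sum()


def generate_spectrum(
    peaks: Sequence[tuple[float, float]],
    baseline_coeffs: Sequence[float] = (0.0,),
    noise_sd: float = 0.0,
    seed: int | None = None,
    mz_min: int = 0,
    mz_max: int = 900,
    peak_width: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    replicate_id: str = "r1",
) -> SpectrumRecord:
    """Simulate one unit-resolution spectrum.

    intensity = polynomial baseline + delta (or narrow Gaussian) peaks +
    heteroscedastic noise, clipped at zero.  Noise SD at each bin is
    ``noise_sd`` times the local noise-free signal plus a small floor of
    2% of the largest signal, mimicking intensity-dependent ion-count
    scatter.
    """
    grid = np.arange(mz_min, mz_max + 1)
    signal = _baseline(baseline_coeffs, grid)
    for mz, height in peaks:
        if height < 0:
            raise ValueError(f"peak height at m/z {mz} must be non-negative")
        if not mz_min <= mz <= mz_max:
            raise ValueError(f"peak m/z {mz} outside grid [{mz_min}, {mz_max}]")
        signal = signal + _peak_profile(grid, mz, height, peak_width)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        floor = 0.02 * signal.max() if signal.size else 0.0
        sd = noise_sd * (np.abs(signal) + floor)
        signal = signal + rng.normal(0.0, 1.0, size=grid.size) * sd
    intensities = np.clip(signal, 0.0, None)
    return SpectrumRecord(
        sample_id=sample_id,
        replicate_id=replicate_id,
        mz_values=grid.astype(float),
        intensities=intensities,
    )


def _draw_scores(
    rng: np.random.Generator, group: str, score_effect: dict[str, float]
) -> dict[str, float]:
    scores: dict[str, float] = {}
    for symptom, (cg_mean, sd, default_shift) in SCORE_MODEL.items():
        shift = score_effect.get(symptom, default_shift)
        mean = cg_mean + (shift if group == CASE else 0.0)
        lo, hi = SCALE_RANGES[symptom]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        val = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
        if symptom in ("HAM", "TAMPA"):  # integer-valued instruments
            val = float(np.clip(round(val), lo, hi))
        scores[symptom] = val
    return scores


def generate_cohort(
    config: CohortConfig,
) -> tuple[SpectralMatrix, list[ClinicalRecord], SyntheticTruth]:
    """Generate a replicate-level spectral matrix, clinical records and truth.

    Each sample draws per-peak height factors (CV ``peak_height_cv``)
    shared by its replicates; FG samples additionally receive the
    configured case-peak increments.  Replicates differ only by noise.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.arange(config.mz_min, config.mz_max + 1)
    n_total = config.n_control + config.n_case

    rows, sample_ids, replicate_ids, labels = [], [], [], []
    baselines = []
    clinical: list[ClinicalRecord] = []
    score_rows = []
    base = _baseline(config.baseline_coeffs, grid)

    groups = [CONTROL] * config.n_control + [CASE] * config.n_case
    for i, group in enumerate(groups):
        sid = f"{group}{i + 1:03d}"
        peaks: list[tuple[float, float]] = []
        for mz, height in config.shared_peaks:
            factor = max(1.0 + config.peak_height_cv * rng.standard_normal(), 0.05)
            peaks.append((mz, height * factor))
        if group == CASE:
            for mz, inc in config.case_peaks:
                factor = max(1.0 + config.peak_height_cv * rng.standard_normal(), 0.05)
                peaks.append((mz, inc * factor))
        for r in range(config.n_replicates):
            rec = generate_spectrum(
                peaks,
                config.baseline_coeffs,
                config.noise_sd,
                rng=rng,
                mz_min=config.mz_min,
                mz_max=config.mz_max,
                peak_width=config.peak_width,
                sample_id=sid,
                replicate_id=f"r{r + 1}",
            )
            rows.append(rec.intensities)
            sample_ids.append(sid)
            replicate_ids.append(f"r{r + 1}")
            labels.append(group)
            baselines.append(base)
        scores = _draw_scores(rng, group, config.score_effect)
        clinical.append(ClinicalRecord(sid, group, dict(scores)))
        score_rows.append({"sample_id": sid, "group": group, **scores})

    X = np.vstack(rows) if rows else np.empty((0, grid.size))
    matrix = SpectralMatrix(
        X=X,
        mz_axis=grid,
        sample_ids=sample_ids,
        labels=np.asarray(labels, dtype=object),
        replicate_ids=replicate_ids,
    )
    matrix.log(
        f"synthetic cohort: {config.n_control} CG + {config.n_case} FG, "
        f"{config.n_replicates} replicates, m/z [{config.mz_min}, {config.mz_max}], "
        f"seed={config.seed}"
    )
    truth = SyntheticTruth(
        planted_case_mz={int(mz) for mz, _ in config.case_peaks},
        true_labels={f"{g}{i + 1:03d}": g for i, g in enumerate(groups)},
        true_baselines=(
            np.vstack(baselines) if baselines else np.empty((0, grid.size))
        ),
        score_table=pd.DataFrame(
            score_rows, columns=["sample_id", "group", *SCORE_MODEL]
        ),
        config=config,
    )
    return matrix, clinical, truth


def write_cohort(
    matrix: SpectralMatrix,
    clinical: list[ClinicalRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Serialize a cohort as matrix CSV + clinical CSV + truth JSON.

    The truth JSON stores planted m/z, labels, scores and the baseline
    polynomial coefficients (per-spectrum baseline vectors are
    reconstructible from those and are not serialized).
    """
    from .io import write_clinical, write_matrix_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "spectra_matrix.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.json",
    }
    write_matrix_csv(matrix, paths["matrix"])
    write_clinical(clinical, paths["clinical"])
    payload = {
        "planted_case_mz": sorted(truth.planted_case_mz),
        "true_labels": truth.true_labels,
        "baseline_coeffs": list(truth.config.baseline_coeffs),
        "score_table": truth.score_table.to_dict(orient="records"),
        "seed": truth.config.seed,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
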