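"""End-to-end pipeline orchestration.

One :class:`RunConfig` (YAML-loadable) drives the full workflow: obtain
a cohort (synthetic or from files), preprocess (per-replicate AWLS,
replicate averaging), assemble symptom-level datasets, ROI-filter and
Kennard–Stone split each dataset, run the 9-model grid, then pool
triplicate GA selections into the cross-dataset variable tally, run the
loadings-difference analysis per dataset, and annotate the highlighted
m/z against a local compound table.  Every artifact is stamped with a
config hash and the seeds used; re-running an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import classify, interpret, io, partition, preprocess, reduce, synthetic

logger = logging.getLogger(__name__)

__all__ = ["DatasetSpec", "RunConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class DatasetSpec:
    symptom: str
    levels: list[str]

    @property
    def name(self) -> str:
        return f"{self.symptom}_{'+'.join(self.levels)}"


DEFAULT_DATASETS = [
    DatasetSpec("CAT", ["moderate"]),
    DatasetSpec("VAS", ["moderate"]),
    DatasetSpec("TAMPA", ["moderate", "severe"]),
]


@dataclass
class RunConfig:
    # exactly one input source: synthetic cohort or file paths
    synthetic: synthetic.CohortConfig | None = None
    spectra_path: str | None = None
    clinical_path: str | None = None
    compound_table_path: str | None = None
    datasets: list[DatasetSpec] = field(default_factory=lambda: list(DEFAULT_DATASETS))
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    train_frac: float = 0.7
    grid: classify.GridConfig = field(default_factory=classify.GridConfig)
    ga_seeds: tuple[int, int, int] = (1, 2, 3)
    tally_threshold: int = 2
    depth_frac: float = 0.2
    annotation_tolerance: float = 0.1
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.spectra_path is not None and self.clinical_path is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError("configure exactly one input source: synthetic or file paths")

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def asdict_safe(obj) -> dict:
    out = {}
    for k, v in vars(obj).items():
        if hasattr(v, "__dataclass_fields__"):
            out[k] = asdict_safe(v)
        elif isinstance(v, (list, tuple)) and v and hasattr(v[0], "__dataclass_fields__"):
            out[k] = [asdict_safe(x) for x in v]
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist()
        else:
            out[k] = v if isinstance(v, (str, int, float, bool, type(None), list, tuple, dict)) else str(v)
    return out


@dataclass
class PipelineResult:
    reports: dict[str, classify.PerformanceReport]
    ga_runs: dict[str, list[reduce.ReductionResult]]
    tally: interpret.VariableTally | None
    loadings: dict[str, interpret.LoadingsDiffReport]
    annotations: list[interpret.AnnotationHit]
    skipped: dict[str, str]
    provenance: list[str]
    config_hash: str


def _load_cohort(config: RunConfig):
    if config.synthetic is not None:
        matrix, clinical, _ = synthetic.generate_cohort(config.synthetic)
        return matrix, clinical
    records = io.read_spectra(config.spectra_path, format="matrix-csv")
    mz_min = int(min(r.mz_values.min() for r in records))
    mz_max = int(max(r.mz_values.max() for r in records))
    matrix = io.average_replicates(records, mz_min, mz_max)
    # re-attach labels from the matrix csv when present
    label_of = {r.sample_id: r.label for r in records}
    matrix.labels = np.asarray([label_of.get(s) for s in matrix.sample_ids], dtype=object)
    clinical = io.read_clinical(config.clinical_path)
    return matrix, clinical


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow for every configured dataset."""
    chash = config.config_hash()
    provenance = [f"pipeline run, config hash {chash}"]
    matrix, clinical = _load_cohort(config)
    provenance.extend(matrix.provenance)

    # AWLS per replicate spectrum, then average replicates; ROI is applied
    # per dataset below, after symptom-level assembly.
    corrected = preprocess.preprocess_matrix(matrix, config.preprocess, apply_roi=False)
    provenance.extend(corrected.provenance[len(matrix.provenance):])

    reports: dict[str, classify.PerformanceReport] = {}
    ga_runs: dict[str, list[reduce.ReductionResult]] = {}
    loadings: dict[str, interpret.LoadingsDiffReport] = {}
    skipped: dict[str, str] = {}

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for spec in config.datasets:
        name = spec.name
        try:
            dataset = io.assemble_dataset(corrected, clinical, spec.symptom, spec.levels)
            dataset, _ = preprocess.roi_filter(dataset, config.preprocess)
        except ValueError as exc:
            skipped[name] = str(exc)
            logger.warning("dataset %s skipped: %s", name, exc)
            continue
        split = partition.kennard_stone(dataset.X, config.train_frac)
        ytr = dataset.labels[split.train_idx].astype(str)
        if np.unique(ytr).size < 2:
            skipped[name] = "a class is absent from the Kennard-Stone training set"
            continue
        counts = dataset.class_counts()
        provenance.append(
            f"dataset {name}: CG={counts.get(io.CONTROL, 0)} FG={counts.get(io.CASE, 0)}, "
            f"p={dataset.n_variables}, train={len(split.train_idx)} test={len(split.test_idx)}"
        )
        report = classify.run_grid(dataset, split, config.grid)
        report.dataset = name
        reports[name] = report

        Xtr = dataset.X[split.train_idx]
        ga_runs[name] = reduce.run_triplicate_ga(
            Xtr, ytr, dataset.mz_axis,
            config.grid.max_vars, config.grid.ga_generations, config.grid.ga_pop,
            config.grid.cost, seeds=config.ga_seeds,
        )
        pca = reduce.pca_fit(Xtr, n_pc=min(config.grid.n_pc, min(Xtr.shape[0] - 1, dataset.n_variables)))
        loadings[name] = interpret.loadings_difference(dataset, pca, config.depth_frac)

        if outdir:
            report.to_csv(outdir / f"grid_{name}.csv")
            partition.write_split(split, dataset.sample_ids, outdir / f"split_{name}.csv")

    all_runs = [r for runs in ga_runs.values() for r in runs]
    tally = interpret.tally_ga_variables(all_runs, config.tally_threshold) if all_runs else None

    highlighted = sorted(
        set(tally.retained if tally else [])
        | {v for rep in loadings.values() for v in rep.selected_mz}
    )
    annotations: list[interpret.AnnotationHit] = []
    if config.compound_table_path and highlighted:
        table = interpret.load_compound_table(config.compound_table_path)
        annotations = interpret.annotate_mz(
            highlighted, table, tolerance=config.annotation_tolerance
        )

    provenance.append(
        f"tally: {len(tally.counts) if tally else 0} distinct GA variables, "
        f"{len(tally.retained) if tally else 0} retained at threshold "
        f"{config.tally_threshold}"
    )
    result = PipelineResult(
        reports=reports,
        ga_runs=ga_runs,
        tally=tally,
        loadings=loadings,
        annotations=annotations,
        skipped=skipped,
        provenance=provenance,
        config_hash=chash,
    )
    if outdir:
        _write_artifacts(result, config, outdir)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    if result.tally:
        result.tally.to_dataframe().to_csv(outdir / "ga_variable_tally.csv", index=False)
    interpret.annotation_to_dataframe(result.annotations).to_csv(
        outdir / "annotations.csv", index=False
    )
    summary = {
        "config_hash": result.config_hash,
        "skipped": result.skipped,
        "loadings_selected": {k: v.selected_mz for k, v in result.loadings.items()},
        "ga_selected": {
            k: [r.selected_mz for r in runs] for k, runs in result.ga_runs.items()
        },
        "ga_seeds": list(config.ga_seeds),
        "provenance": result.provenance,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclasses)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        syn = dict(raw["synthetic"] or {})
        for key in ("shared_peaks", "case_peaks"):
            if key in syn:
                syn[key] = [tuple(x) for x in syn[key]]
        kwargs["synthetic"] = synthetic.CohortConfig(**syn)
    for key in ("spectra_path", "clinical_path", "compound_table_path", "train_frac",
                "tally_threshold", "depth_frac", "annotation_tolerance", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "ga_seeds" in raw:
        kwargs["ga_seeds"] = tuple(raw["ga_seeds"])
    if "datasets" in raw:
        kwargs["datasets"] = [DatasetSpec(d["symptom"], list(d["levels"])) for d in raw["datasets"]]
    if "preprocess" in raw:
        kwargs["preprocess"] = preprocess.PreprocessConfig(**raw["preprocess"])
    if "grid" in raw:
        grid = dict(raw["grid"])
        if "svm_kernel" in grid:
            grid["svm_kernel"] = classify.PolyKernel(**grid["svm_kernel"])
        if "cost" in grid:
            grid["cost"] = reduce.CostSpec(**grid["cost"])
        kwargs["grid"] = classify.GridConfig(**grid)
    return RunConfig(**kwargs)
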