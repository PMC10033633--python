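"""Discover and annotate discriminative m/z variables.

Two complementary routes over the same symptom-level datasets as the
model grid:

1. GA tally — run the genetic-algorithm selection in triplicate per
   dataset (the GA is stochastic), pool the selected m/z sets, and keep
   variables occurring at least twice.
2. Loadings difference — compute d = mean(CG) − mean(FG) per dataset
   and select its negative peaks (case-elevated m/z) that coincide with
   local extrema of the PC1 loadings.

The union of highlighted variables is annotated as [M+H]+ ions against
the synthetic compound table (± 0.1 m/z).  Writes tally, selection and
annotation CSVs plus a difference-spectrum figure under
results/interpretation/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibropsi.interpret import (
    annotate_mz,
    annotation_to_dataframe,
    load_compound_table,
    loadings_difference,
    tally_ga_variables,
)
from fibropsi.io import assemble_dataset, read_clinical, read_matrix_csv
from fibropsi.partition import kennard_stone
from fibropsi.pipeline import DEFAULT_DATASETS
from fibropsi.preprocess import PreprocessConfig, roi_filter
from fibropsi.reduce import pca_fit, run_triplicate_ga

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument(
        "--matrix", type=Path,
        default=ROOT / "results" / "preprocessed" / "corrected_matrix.csv",
    )
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "interpretation")
    ap.add_argument("--ga-seeds", type=int, nargs=3, default=(1, 2, 3))
    ap.add_argument(
        "--compound-table", type=Path,
        default=ROOT / "data" / "compounds" / "synthetic_compound_table.csv",
    )
    args = ap.parse_args()

    corrected = read_matrix_csv(args.matrix)
    clinical = read_clinical(args.cohort / "clinical.csv")
    args.outdir.mkdir(parents=True, exist_ok=True)

    all_runs, loadings_selected = [], {}
    diff_reports = {}
    for spec in DEFAULT_DATASETS:
        dataset = assemble_dataset(corrected, clinical, spec.symptom, spec.levels)
        dataset, _ = roi_filter(dataset, PreprocessConfig())
        split = kennard_stone(dataset.X, 0.7)
        Xtr = dataset.X[split.train_idx]
        ytr = dataset.labels[split.train_idx].astype(str)
        runs = run_triplicate_ga(Xtr, ytr, dataset.mz_axis, seeds=args.ga_seeds)
        all_runs.extend(runs)
        print(f"{spec.name}: GA triplicate selected {[r.selected_mz for r in runs]}")
        pca = pca_fit(Xtr, n_pc=5)
        rep = loadings_difference(dataset, pca, depth_frac=0.2)
        loadings_selected[spec.name] = rep.selected_mz
        diff_reports[spec.name] = rep
        print(f"{spec.name}: loadings-difference selected {rep.selected_mz}")

    tally = tally_ga_variables(all_runs, threshold=2)
    tally.to_dataframe().to_csv(args.outdir / "ga_variable_tally.csv", index=False)
    print(
        f"\nGA tally: {len(tally.counts)} distinct variables across "
        f"{len(all_runs)} runs; {len(tally.retained)} occur >= 2 times: "
        f"{tally.retained}"
    )
    pd.DataFrame(
        [(k, ";".join(map(str, v))) for k, v in loadings_selected.items()],
        columns=["dataset", "selected_mz"],
    ).to_csv(args.outdir / "loadings_selected.csv", index=False)

    highlighted = sorted(
        set(tally.retained) | {v for vs in loadings_selected.values() for v in vs}
    )
    table = load_compound_table(args.compound_table)
    hits = annotate_mz(highlighted, table, tolerance=0.1)
    annotation_to_dataframe(hits).to_csv(args.outdir / "annotations.csv", index=False)
    print(f"highlighted m/z: {highlighted}")
    for h in hits:
        print(
            f"  m/z {h.query_mz:.0f} -> {h.name} ({h.compound_class}), "
            f"mass error {h.mass_error:+.3f}"
        )

    _plot(diff_reports, args.outdir)
    print(f"artifacts -> {args.outdir.relative_to(ROOT)}")


def _plot(reports: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(reports), 1, figsize=(9, 2.8 * len(reports)), sharex=True)
    if len(reports) == 1:
        axes = [axes]
    for ax, (name, rep) in zip(axes, reports.items()):
        ax.plot(rep.mz_axis, rep.difference, lw=0.8, label="mean(CG) − mean(FG)")
        scale = abs(rep.difference).max() / (abs(rep.pc1_loading).max() or 1.0)
        ax.plot(rep.mz_axis, rep.pc1_loading * scale, lw=0.6, alpha=0.6, label="PC1 loading (scaled)")
        for v in rep.selected_mz:
            ax.axvline(v, color="crimson", ls=":", lw=0.8)
        ax.set_title(f"{name}: selected {rep.selected_mz}", fontsize=9)
        ax.legend(fontsize=7)
    axes[-1].set_xlabel("m/z")
    fig.tight_layout()
    fig.savefig(outdir / "difference_spectra.png", dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
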