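"""Run the nine-combination model grid on symptom-level datasets.

For each configured symptom/level dataset: assemble cases at the given
levels (all controls retained), apply the 3% ROI filter, split 70/30 by
Kennard–Stone, train PCA/SPA/GA × LDA/QDA/SVM, and score sensitivity,
specificity and accuracy on the held-out test set.  Writes one grid CSV
per dataset plus a combined best-model table under results/grids/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibropsi.classify import GridConfig, run_grid
from fibropsi.io import assemble_dataset, read_clinical, read_matrix_csv
from fibropsi.partition import kennard_stone, write_split
from fibropsi.pipeline import DEFAULT_DATASETS
from fibropsi.preprocess import PreprocessConfig, roi_filter

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument(
        "--matrix", type=Path,
        default=ROOT / "results" / "preprocessed" / "corrected_matrix.csv",
    )
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "grids")
    ap.add_argument("--ga-seed", type=int, default=1)
    args = ap.parse_args()

    corrected = read_matrix_csv(args.matrix)
    clinical = read_clinical(args.cohort / "clinical.csv")
    args.outdir.mkdir(parents=True, exist_ok=True)
    config = GridConfig(ga_seed=args.ga_seed)

    best_rows = []
    for spec in DEFAULT_DATASETS:
        dataset = assemble_dataset(corrected, clinical, spec.symptom, spec.levels)
        dataset, _ = roi_filter(dataset, PreprocessConfig())
        split = kennard_stone(dataset.X, 0.7)
        report = run_grid(dataset, split, config)
        report.dataset = spec.name
        report.to_csv(args.outdir / f"grid_{spec.name}.csv")
        write_split(split, dataset.sample_ids, args.outdir / f"split_{spec.name}.csv")
        counts = dataset.class_counts()
        best = report.best_row
        print(
            f"{spec.name}: CG={counts['CG']} FG={counts['FG']} "
            f"(train {report.n_train} / test {report.n_test}); best "
            f"{best.model_name} Sens={best.sens:.0f}% Spec={best.spec:.0f}% "
            f"AC={best.accuracy:.0f}%"
        )
        best_rows.append(
            {
                "dataset": spec.name, "CG": counts["CG"], "FG": counts["FG"],
                "best_model": best.model_name, "Sens_pct": best.sens,
                "Spec_pct": best.spec, "AC_pct": best.accuracy,
            }
        )
    table = pd.DataFrame(best_rows)
    table.to_csv(args.outdir / "best_models.csv", index=False)
    print(f"\nbest-model table -> {(args.outdir / 'best_models.csv').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
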