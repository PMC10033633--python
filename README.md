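# fibropsi

Chemometric classification of paper-spray ionization mass spectra
(PSI-MS) of blood plasma for fibromyalgia case/control discrimination.

Fibromyalgia has no laboratory diagnostic; diagnosis rests on clinical
scales (pain VAS, FIQ, Hamilton anxiety, Tampa kinesiophobia, SF-36
quality of life, pain catastrophizing).  One proposed route to an
objective marker is to classify plasma PSI-MS spectra of patients
stratified by those symptom levels.  This package implements that
workflow end-to-end for chemometricians and mass-spectrometrists:

- **preprocessing** — AWLS (iteratively reweighted polynomial) baseline
  correction per replicate spectrum, replicate averaging, and ROI
  filtering of variables below 3% of the base peak;
- **partitioning** — deterministic Kennard–Stone 70/30 train/test split;
- **reduction** — PCA (5 components), the successive projections
  algorithm (SPA) and a seeded genetic algorithm (GA), both capped at
  10 variables with a leave-one-out LDA cost;
- **classification** — the Mahalanobis discriminant scores

      L_ik = (x_i − x̄_k)ᵀ C_pooled⁻¹ (x_i − x̄_k) − 2 ln π_k          (LDA)
      Q_ik = (x_i − x̄_k)ᵀ C_k⁻¹ (x_i − x̄_k) + ln|C_k| − 2 ln π_k     (QDA)

  and a polynomial-kernel SVM, F(x) = sign(Σ α_i y_i K(x, z_i) + b),
  trained by SMO — a 3 × 3 grid of nine model combinations scored by
  test-set SENS/SPEC/AC with fibromyalgia (FG) as the positive class;
- **interpretation** — triplicate-GA variable tallies (keep m/z
  occurring ≥ 2×), PC1-loadings/mean-difference peak discovery, and
  [M+H]+ annotation against a local compound table (± 0.1 m/z).

Because the originating clinical spectra are not publicly deposited,
the package ships a first-class synthetic cohort generator
(`fibropsi.synthetic`) that plants known case-elevated peaks and
symptom-score structure, so every stage is tested against ground truth.
See `docs/methods.md` for the model details and what the synthetic
conditions do and do not show about real data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic cohort (78 controls, 83 cases, triplicate spectra,
case peaks planted at m/z 301 and 579):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_model_grid.py
python analysis/04_variable_discovery.py
```

which prints (seed 7, the default):

```
cohort: 78 CG + 83 FG samples, 3 replicates each, 901 m/z variables
planted case-elevated m/z: [301, 579]
...
ROI at 3% of the base peak would keep 15 variables: [104, 118, 132, ...]
CAT_moderate: CG=78 FG=73 (train 106 / test 45); best PCA-LDA Sens=100% Spec=100% AC=100%
VAS_moderate: CG=78 FG=63 (train 99 / test 42); best PCA-LDA Sens=100% Spec=100% AC=100%
TAMPA_moderate+severe: CG=78 FG=78 (train 109 / test 47); best PCA-LDA Sens=100% Spec=100% AC=100%
...
CAT_moderate: loadings-difference selected [301, 579]
GA tally: 15 distinct variables across 9 runs; 14 occur >= 2 times: [...]
  m/z 301 -> SynGlycerolipid-301 (glycerolipid), mass error +0.000
  m/z 579 -> SynLysoPC-579 (glycerophospholipid), mass error +0.000
```

Reading this: after baseline correction the 3% ROI filter keeps exactly
the 15 real peaks out of 901 nominal-mass variables; each symptom-level
dataset (cases filtered by level, all controls retained) is split 70/30
by Kennard–Stone; the best of the nine model combinations separates the
planted classes perfectly on the held-out test set; and both discovery
routes — the GA tally and the PC1-loadings/mean-difference analysis —
recover the planted case markers at m/z 301 and 579, which then annotate
as [M+H]+ ions of the (synthetic) compound-table entries.

The same run is available as a library call
(`fibropsi.pipeline.run_pipeline`) or through the CLI:

```bash
fibropsi simulate --outdir results/cohort --seed 7
fibropsi run-all run.yaml --outdir results/run
```

Reference m/z lists from the original clinical application of this
workflow ship under `data/reference_mz/` for documentation and
comparison; they are not test oracles (see the README there).

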