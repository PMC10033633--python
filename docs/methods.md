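# Methods

This package re-implements, as a tested pipeline over synthetic data, a
chemometric workflow for discriminating fibromyalgia cases (FG) from
controls (CG) using positive-mode paper-spray ionization mass spectra
(PSI-MS) of blood plasma, stratified by clinical symptom levels.  The
clinical spectra the workflow was originally applied to are not publicly
deposited, so every stage is exercised end-to-end on a synthetic cohort
generator with known planted structure.

## The synthetic cohort

The generator emulates unit-resolution ion-trap spectra on the integer
m/z grid 0–900:

- a smooth quadratic baseline drift, `b(m) = 30 + 0.08·m − 9·10⁻⁵·m²`
  (arbitrary intensity units, a gentle hump peaking near m/z 450 — a
  plausible chemical-noise envelope for a biofluid spray source);
- 15 shared "plasma" peaks (delta functions by default; an optional
  Gaussian width parameter exists and defaults to 0, matching
  unit-resolution centroided data) with mean heights 150–500 and a
  per-sample, per-peak height coefficient of variation of 0.10 —
  biological plus spotting variability shared by a sample's replicates;
- case-elevated peaks at m/z 301 (+80) and 579 (+150) added to FG
  samples only: these are the planted ground truth every downstream
  stage is tested against;
- heteroscedastic noise per replicate, SD = 0.05 × local signal plus a
  floor of 2% of the spectrum's largest signal, a stand-in for
  intensity-dependent ion-count scatter (the real PSI-MS noise process
  is not characterized; nothing downstream depends on its exact form);
- negative intensities clipped at zero (intensities are counts);
- triplicate acquisition per sample (replicates share the sample's peak
  heights and differ by noise);
- per-patient symptom scores for the six clinical scales (VAS, FIQ,
  HAM, TAMPA, QL, CAT) drawn from class-conditional normals truncated
  to each scale's legal range, with control means in the unaffected
  region and case means placed at the moderate level of each instrument
  (e.g. CAT: CG ~ N(10, 6²), FG ~ N(30, 7²) on 0–60).  HAM and TAMPA
  are rounded to integers.  This is the simplest model that reproduces
  the level structure used for dataset assembly.

Default cohort size is 78 CG / 83 FG, the size of the clinical cohort
this workflow targets.

What the generator does **not** emulate: electrospray physics, isotope
patterns, adduct chemistry, peak-height correlations between compounds,
batch or acquisition-order effects, and realistic metabolite-level
class overlap — the planted two-peak contrast is far cleaner than a
real disease signature.  Passing the recovery tests therefore shows the
pipeline machinery is correct, not that comparable accuracy would be
reached on real plasma spectra.

## Preprocessing

**AWLS baseline correction** is realized as iteratively reweighted
polynomial least squares (order 2 by default): fit, estimate the noise
scale σ from the negative residuals, down-weight (w = 10⁻⁶) points more
than 2σ above the fit, refit.  Iteration stops when the baseline changes
by less than 10⁻⁶ of the spectrum maximum, when the above/below
assignment repeats (a fixed point or limit cycle of the binary
reweighting map — no further refinement is possible), or at 100
iterations (then the last iterate is returned with a logged warning,
never an exception).  The 2σ rule keeps the baseline centred in the
noise band rather than on its lower envelope, which matters because the
ROI threshold below is only 3%.  The corrected spectrum is
`max(y − max(baseline, 0), 0)`, so it is always non-negative and never
exceeds the input.  Correction runs per replicate spectrum, before
averaging (the alternative — correcting the averaged spectrum — differs
only at second order; correcting first is the conservative choice).

**Replicate averaging** collapses the triplicates to one row per sample
before any modeling, so replicates of one sample can never straddle the
train/test split.

**ROI filtering** keeps variable *j* iff `max_i X[i,j] ≥ f · max(X)`
with f = 0.03 — 3% of the dataset's single base peak.  The "below"
complement is available as an option; "above" is the default because it
is the variant that is favorable for classification.  Applied after
dataset assembly (so each symptom-level dataset gets its own retained
set), it typically reduces 901 variables to the ~15 real peaks.

## Dataset assembly

Scores map to levels by the clinical cutoffs: HAM ≤7 none / 8–14 mild /
15–23 moderate / ≥24 severe; TAMPA 17–34 mild / 35–50 moderate / 51–68
severe; FIQ <39 mild / 39–59 moderate / >59 severe; VAS (mm) 0–4 none /
5–44 mild / 45–74 moderate / ≥75 severe; QL quartiles low / regular /
good / excellent; CAT 0–20 mild / 21–40 moderate / 41–60 high.  Two
published ranges are ambiguous: TAMPA leaves 41–50 unassigned and CAT
lists 40 in two levels; here TAMPA "moderate" owns 35–50 and CAT
"moderate" owns 40.  The level filter applies to cases; all controls
with a non-missing score are retained (an option filters both arms).
Assembly refuses datasets where either class has fewer than 4 samples —
grids on such reduced datasets are not feasible.

## Partitioning

Kennard–Stone on the preprocessed intensities (Euclidean distance, no
internal scaling): the most distant pair seeds the training set and each
further member maximizes its minimum distance to the selected set, until
`round(0.7·n)` members (floored at 2 — the seed pair).  Ties break to
the lowest sample index; the split is fully deterministic and is
computed per dataset.  Kennard–Stone does not guarantee both classes in
training; the grid errors out if one is missing.

## Reduction

- **PCA**: mean-centred SVD; 5 components by default; test rows are
  projected with the training mean only.
- **SPA** (successive projections): for every starting variable a chain
  grows by adding the column with maximal norm after orthogonal
  projection onto the complement of the chain's span (minimal
  collinearity); every prefix of every chain is scored and the
  minimum-cost subset wins (ties: fewer variables, then the
  lexicographically smaller m/z set).  Chains are capped at 10
  variables.
- **GA**: binary masks over the variables; fitness = selection cost;
  tournament selection (size 2), single-point crossover (rate 0.8),
  per-bit mutation (rate 1/p), repair of over-cap masks by random
  deactivation, elitism of one; 10 generations × population 10,
  cap 10; fully seeded and deterministic per seed, and run in
  triplicate for tallying because the GA is stochastic.

The **selection cost** shared by SPA and GA is the leave-one-out
misclassification fraction of an equal-prior LDA restricted to the
candidate variables, computed on training rows only.  No validation set
is held out (test rows are reserved for reporting), so an internal
cross-validated risk is the natural fitness; LOO-LDA is the chemometric
convention for these wrapper selectors.  Folds that would leave a class
with fewer than two members are excluded from the denominator.

## Classification

LDA and QDA assign sample x to the class k minimizing

    L_ik = (x − x̄_k)ᵀ C_pooled⁻¹ (x − x̄_k) − 2 ln π_k
    Q_ik = (x − x̄_k)ᵀ C_k⁻¹ (x − x̄_k) + ln|C_k| − 2 ln π_k

with equal priors by default (the cohorts are near-balanced).
Covariances receive a ridge ε·(tr C/p)·I with ε = 10⁻⁸, escalated by
decades (with a warning) if the matrix is still not positive definite.

The SVM solves the soft-margin dual by SMO with a polynomial kernel
K(x, z) = (γ xᵀz + c0)^d, deciding by sign(Σ αᵢyᵢK(x, zᵢ) + b) over the
support vectors.  Defaults: d = 2, c0 = 1, C = 1, and
γ = 1/(p·Var(X_train)) — the common "scale" convention, chosen because
raw ion-count features span orders of magnitude and a fixed γ = 1/p
makes the kernel numerically unstable on PCA scores.  The SMO
second-choice heuristic (max |E_i − E_j|) falls back to a deterministic
scan; a dual-objective stall detector stops micro-step limit cycles;
the bias is recomputed from the non-bound support vectors at the end.
Non-convergence at the iteration cap yields a warning carrying the
attained KKT violation, not an exception (this occurs mainly on
signal-free, non-separable data, where the fitted model is at chance
anyway).

**The grid** trains the nine reduction × classifier combinations
(PCA/SPA/GA × LDA/QDA/SVM), each reduction fitted once on training rows
and shared by its classifiers.  Metrics are computed on the test set
only, with FG the positive class: SENS = 100·TP/(TP+FN),
SPEC = 100·TN/(TN+FP), AC = 100·(TP+TN)/total; zero denominators report
NaN with a warning.  A failing combination is marked `failed` and the
grid continues.  The best model maximizes accuracy with ties broken by
sensitivity then specificity (the reporting convention here; any
monotone rule would do).

## Variable interpretation

- **GA tally**: selected m/z sets are pooled over all GA runs (triplicate
  × datasets); variables occurring at least twice are retained.  A
  variable appearing in one run counts once for that run.
- **Loadings difference**: d = mean(CG) − mean(FG) per m/z; local minima
  of d with depth ≥ 0.2·max|d| (the depth fraction is a required report
  field; there is no canonical value) are case-elevated candidates;
  each must coincide within ±1 m/z with a local extremum (either sign)
  of the PC1 loading vector.  Swapping the class labels negates d and
  selects the mirror peaks.
- **Annotation**: query m/z v hits a compound of neutral monoisotopic
  mass M when |v − (M + 1.00728)| ≤ 0.1 — protonated molecular ions
  [M+H]+ with the charge-corrected proton mass, not the hydrogen atom
  mass.  Matching is against a local compound-table CSV; the shipped
  table is synthetic (see `data/compounds/README.md`).  No online
  database queries and no MS/MS logic.

## Problem sizes and determinism

The test suite and the acceptance script use the default cohort
(78 + 83 samples × 3 replicates × 901 variables) for end-to-end checks
and 20 + 20 cohorts for unit-level work; SPA/GA selection always runs on
post-ROI matrices (~15 variables), where the LOO-LDA cost is cheap.
Every stochastic stage (generator, GA, permutation null) takes an
explicit seed recorded in its result object, and identical configs
reproduce identical outputs bit for bit.

A note on the permutation null: the "best model" is selected from nine
correlated accuracies, so its null distribution is wider than a single
binomial proportion; the null check therefore uses the Šidák-adjusted
95% band for the maximum of nine proportions around 50%.

## Known limitations

- The AWLS variant here is an iteratively reweighted polynomial fit;
  commercial implementations of the same name may differ in weighting
  details.  Only the order-2 default is exercised heavily.
- SPA cost evaluation is O(p² · LOO) and is intended for post-ROI
  variable counts (tens), not raw 901-variable matrices.
- The SMO solver targets the small dense problems this pipeline
  produces (n ≲ 200); it is not a general-purpose SVM.
- Binary classification only; no probability calibration or ROC
  analysis; no profile-mode peak picking or lock-mass recalibration.
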