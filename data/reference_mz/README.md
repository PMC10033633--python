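# Reference m/z lists

Variable lists reported for the clinical plasma cohort that this
workflow was originally applied to:

- `doubled_ga_variables.csv` — the 31 m/z values that occurred in more
  than one GA model run across the symptom-level datasets (the
  "doubled" tally at threshold 2).
- `pc1_selected_variables.csv` — the five m/z values highlighted by the
  PC1-loadings / class-mean-difference analysis across all symptom
  levels.

These lists document the original findings for comparison and
regression-style inspection only.  They derive from plasma spectra that
are not publicly deposited and are therefore **not** used as test
oracles anywhere in this package.
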