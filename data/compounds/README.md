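# Synthetic compound table

`synthetic_compound_table.csv` is a constructed ([M+H]+ demonstration)
compound table whose neutral monoisotopic masses are placed so that the
protonated ions of the first five entries fall on the integer m/z values
planted by the synthetic cohort generator (observed m/z = neutral mass
+ 1.00728).  It stands in for a local extract of a metabolite/lipid
database, which cannot be redistributed here; every entry is synthetic
and the names say so.
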