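mz
5
31
72
131
133
160
225
252
255
259
336
365
366
375
389
391
413
449
478
492
530
645
646
679
707
797
827
841
846
848
888
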