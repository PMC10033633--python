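mz
301
311
325
338
579
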