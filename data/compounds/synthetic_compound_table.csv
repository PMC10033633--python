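name,neutral_monoisotopic_mass,class
SynLysoPC-579,577.99272,glycerophospholipid
SynGlycerolipid-301,299.99272,glycerolipid
SynSphingolipid-325,323.99272,sphingolipid
SynSteroid-338,336.99272,steroids and derivatives
SynFattyEster-311,309.99272,fatty esters
SynDecoy-450,449.35000,fatty acids
SynDecoy-620,619.42000,glycerophospholipid
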