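label,epsilon,sigma
C,0.080,3.500
N(NT),0.203,3.215
B(NT),0.453,3.380
S,0.250,3.550
N,0.170,3.250
H,0.018,0.094
H on C,0.050,2.500
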