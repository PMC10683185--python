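bond,r_angstrom,rho,laplacian,e_int_kcal,G,V,gvr_printed
C240-O220...B31,2.55,0.014615,0.050073,3.49,0.011823,-0.011128,1.062
C244-O222...N58,3.14,0.008680,0.033855,1.90,0.007260,-0.006055,1.199
C244-O222...N33,3.01,0.009077,0.031465,1.99,0.007105,-0.006345,1.120
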