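species,C1,C2,O1,O2,O3,N1,N2,N3,N4,S,O_S,H2,H3
SSZ_enol,0.2,0.44,-0.3,-0.34,-0.31,-0.21,-0.20,-0.60,-0.40,0.90,-0.47,0.25,0.28
SSZ_keto,0.24,0.41,-0.28,-0.3,-0.28,-0.32,-0.18,-0.60,-0.41,0.90,-0.47,0.25,0.28
enol_carbonyl_ver1,0.28,0.45,-0.61,-0.57,-0.40,-0.30,-0.29,-0.57,-0.57,0.49,-0.10,0.40,0.38
enol_carbonyl_ver2,0.28,0.45,-0.60,-0.57,-0.40,-0.30,-0.29,-0.57,-0.57,0.49,-0.10,0.40,0.38
enol_sulfonamide,0.25,0.46,-0.57,-0.39,-0.57,-0.31,-0.29,-0.60,-0.57,0.72,-0.13,0.39,0.38
keto_carbonyl_ver1,0.42,0.69,-0.45,-0.54,-0.42,-0.61,-0.33,-0.74,-0.57,0.49,-0.12,0.37,0.36
keto_carbonyl_ver2,0.30,0.48,-0.43,-0.59,-0.37,-0.6,-0.22,-0.56,-0.57,0.49,-0.12,0.41,0.38
keto_sulfonamide,0.29,0.52,-0.52,-0.60,-0.43,-0.6,-0.20,-0.60,-0.56,0.67,-0.13,0.42,0.38
keto_pyridine,0.27,0.47,-0.38,-0.55,-0.34,-0.61,-0.22,-0.56,-0.47,0.63,-0.17,0.37,0.48
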