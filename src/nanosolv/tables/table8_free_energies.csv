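species,dg_sol_printed,dg_sol,dg_ass_printed
BNNT,-248.2917,-248.2917,
SSZ_enol,-21.134,-21.134,
SSZ_keto,-21.7606,-21.7606,
enol_carbonyl_ver1,-223.0949,-223.0949,-46.3308
enol_carbonyl_ver2,-223.4236,-223.4236,-46.0021
enol_sulfonamide,-220.2629,-220.2629,-49.1628
keto_carbonyl_ver1,234.464,-234.464,-35.5883
keto_carbonyl_ver2,-225.7073,-225.7073,-44.345
keto_sulfonamide,-222.5613,-222.5613,-47.491
keto_pyridine,-206.97,-206.97,-63.08
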