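metabolite,group,cs_sh_35,sig_35,cs_sh_25,sig_25
"Butanoate 2,4-dihydroxy",amino acids,1.34,1,1.38,1
Glu,amino acids,1.25,0,1.45,1
Maleate,organic acids,0.63,1,0.67,1
Malate,organic acids,0.32,1,0.50,1
Phosphorate,organic acids,1.23,0,1.51,1
Glutarate,organic acids,0.81,1,1.11,0
4-Hydroxy cis-cinnamic acid,organic acids,1.43,1,1.26,0
Quinate,organic acids,0.58,0,0.33,1
5-caffeoyl trans-quinate,organic acids,33.83,1,13.65,1
Threonate,organic acids,0.45,1,0.37,1
Ascorbate,organic acids,1.24,1,1.11,0
Glucuronate,organic acids,0.52,1,0.41,1
Galactonate,organic acids,0.70,1,0.75,1
Caffeate,organic acids,0.99,0,0.82,1
Catechin,others,0.50,1,0.87,0
Epigallocatechin,others,1.49,1,2.37,1
Epicatechin,others,0.60,1,0.93,0
Glucose,sugars,0.71,1,0.68,1
Raffinose,sugars,0.56,1,0.97,0
Xylose,sugars,0.74,1,0.72,1
Lyxose,sugars,0.84,0,0.81,1
Ribulose,sugars,1.92,1,1.61,1
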