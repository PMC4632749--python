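metabolite,group,cs_35_25,cs_significant,sh_35_25,sh_significant
Ala,amino acids,1.38,1,1.60,1
Gly,amino acids,0.66,1,0.69,1
Ser,amino acids,0.41,1,0.54,1
Glu,amino acids,0.47,1,0.64,0
Asp,amino acids,1.67,0,1.71,1
Citrate,organic acids,1.39,0,1.64,1
Malate,organic acids,0.36,1,0.57,1
Maleate,organic acids,0.72,1,0.77,1
Succinate,organic acids,0.48,1,0.52,1
Threonate,organic acids,0.67,0,0.55,1
"Threonate-1,4-lactone",organic acids,0.71,1,0.74,0
Glycerate,organic acids,0.56,1,0.51,1
Malonate,organic acids,1.26,1,1.19,0
Phosphorate,organic acids,1.25,0,1.53,1
Erythronate,organic acids,1.53,1,2.08,1
Glutarate 2-oxo,organic acids,0.71,1,0.96,0
Arabinonic acid,organic acids,1.38,0,1.61,1
4-Hydroxy trans-cinnamic acid,organic acids,1.79,1,1.52,1
4-Hydroxy cis-cinnamic acid,organic acids,1.27,1,1.11,0
Shikimate,organic acids,0.74,0,0.85,0
Dehydroascorbate,organic acids,0.74,1,0.71,1
Ascorbate,organic acids,1.28,1,1.15,0
Glucuronate,organic acids,1.36,1,1.45,1
cis-Caffeate,organic acids,1.28,1,1.16,0
Galactonate,organic acids,1.54,1,1.64,1
trans-Caffeate,organic acids,1.32,1,1.09,0
Fructose,sugars,0.90,0,0.53,1
Glucose,sugars,0.61,1,0.40,1
Glucose-6-phosphate,sugars,0.62,1,0.62,1
Sucrose,sugars,0.68,1,0.63,1
Xylose,sugars,0.84,0,0.82,1
Fucose,sugars,1.53,1,1.82,1
Ribulose,sugars,1.70,1,1.44,1
Raffinose,sugars,1.81,1,3.13,1
Putrescine,others,0.28,1,0.34,1
Epicatechin,others,0.55,1,0.85,0
Catechin,others,0.79,0,1.37,1
Epigallocatechin,others,0.99,0,1.57,1
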