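metabolite	class
Ala	amino acid
Gly	amino acid
Ser	amino acid
Glu	amino acid
Asp	amino acid
Thr	amino acid
GABA	amino acid
Pyroglutamate	amino acid
Putrescine	amino acid
Butanoate 2,4-dihydroxy	amino acid
Citrate	TCA cycle
Malate	TCA cycle
Succinate	TCA cycle
Glutarate 2-oxo	TCA cycle
Glucose	glycolysis
Fructose	glycolysis
Sucrose	glycolysis
Glucose-6-phosphate	glycolysis
Xylose	non-glycolytic sugar
Fucose	non-glycolytic sugar
Ribulose	non-glycolytic sugar
Raffinose	non-glycolytic sugar
Lyxose	non-glycolytic sugar
Catechin	flavonoid
Epicatechin	flavonoid
Epigallocatechin	flavonoid
Quinate	flavonoid
5-caffeoyl trans-quinate	flavonoid
Shikimate	flavonoid
cis-Caffeate	flavonoid
trans-Caffeate	flavonoid
Caffeate	flavonoid
4-Hydroxy trans-cinnamic acid	flavonoid
4-Hydroxy cis-cinnamic acid	flavonoid
Maleate	carboxylic acid
Threonate	carboxylic acid
Threonate-1,4-lactone	carboxylic acid
Glycerate	carboxylic acid
Malonate	carboxylic acid
Phosphorate	carboxylic acid
Erythronate	carboxylic acid
Glutarate	carboxylic acid
Arabinonic acid	carboxylic acid
Dehydroascorbate	carboxylic acid
Ascorbate	carboxylic acid
Glucuronate	carboxylic acid
Galactonate	carboxylic acid
Tartarate	carboxylic acid
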