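item	category	in_vivo	in_silico	result
D-Glucose	carbon_source	+	+	TP
Fructose	carbon_source	+	+	TP
D-Ribose	carbon_source	-	-	TN
Threhalose	carbon_source	+	+	TP
Cellobiose	carbon_source	+	+	TP
D-Deoxyribose	carbon_source	-	-	TN
D-Xylose	carbon_source	-	-	TN
L-Arabinose	carbon_source	-	-	TN
L-Rhammose	carbon_source	-	-	TN
D-Mannose	carbon_source	-	-	TN
Esculin	carbon_source	+	-	FN
Salicin	carbon_source	+	-	FN
Glycerol	carbon_source	-	-	TN
D-Mannitol	carbon_source	-	-	TN
L-Sorbitol	carbon_source	-	-	TN
L-Malic acid	carbon_source	-	-	TN
Citric acid	carbon_source	-	-	TN
Fumaric acid	carbon_source	-	-	TN
Adenine	nucleotide	+	+	TP
Guanine	nucleotide	+	+	TP
Xanthine	nucleotide	+	+	TP
Cytosine	nucleotide	+	+	TP
Thymine	nucleotide	+	+	TP
Uracil	nucleotide	+	+	TP
MnSO4.4H2O	mineral	-	-	TN
MgSO4.7H2O	mineral	+	+	TP
K2HPO4	mineral	-	-	TN
CaCl2	mineral	+	+	TP
CuSO4.5H2O	mineral	+	+	TP
FeSO4.7H2O	mineral	+	+	TP
ZnSO4.7H2O	mineral	+	+	TP
L-Alanine	amino_acid	+	+	TP
L-Arginine	amino_acid	-	-	TN
L-Asparagine	amino_acid	+	+	TP
L-Aspartic acid	amino_acid	+	+	TP
L-Cysteine	amino_acid	-	-	TN
L-Glutamic acid	amino_acid	-	+	FP
L-Glutamine	amino_acid	+	+	TP
L-Glycine	amino_acid	+	+	TP
L-Histidine	amino_acid	-	-	TN
L-Isoleucine	amino_acid	-	-	TN
L-Leucine	amino_acid	-	-	TN
L-Lysine	amino_acid	+	+	TP
L-Methionine	amino_acid	-	-	TN
L-Phenylalanine	amino_acid	-	-	TN
L-Proline	amino_acid	+	+	TP
L-Serine	amino_acid	+	-	FN
L-Threonine	amino_acid	-	-	TN
L-Tryptophan	amino_acid	-	-	TN
L-Tyrosine	amino_acid	-	-	TN
L-Valine	amino_acid	-	-	TN
4-Aminobenzoic acid	vitamin	+	+	TP
Biotin	vitamin	+	+	TP
Choline	vitamin	+	+	TP
Cyanocobalamin	vitamin	+	+	TP
Folic acid	vitamin	+	+	TP
Nicotinic acid	vitamin	-	-	TN
D-Pantothenate	vitamin	-	-	TN
Pyridoxine	vitamin	+	+	TP
Riboflavin	vitamin	+	+	TP
Thiamine	vitamin	+	+	TP
myo-Inositol	vitamin	+	+	TP
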