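Compound,Class,Method,PreAverage,PostAverage,RecoveryPercent
4-Aminobutyric acid (GABA),amino_acid,Method 1,0.00,0.74,0.00
4-Aminobutyric acid (GABA),amino_acid,Method 2,0.00,0.95,0.00
4-Aminobutyric acid (GABA),amino_acid,Method 3,0.00,0.84,0.00
4-Aminobutyric acid (GABA),amino_acid,Method 4,0.00,0.23,0.00
4-Aminobutyric acid (GABA),amino_acid,Method 5,0.11,0.35,30.46
L-Alanine,amino_acid,Method 1,0.00,3.06,0.00
L-Alanine,amino_acid,Method 2,0.00,4.01,0.00
L-Alanine,amino_acid,Method 3,0.00,3.70,0.00
L-Alanine,amino_acid,Method 4,0.00,1.79,0.00
L-Alanine,amino_acid,Method 5,1.85,3.01,61.35
L-Leucine,amino_acid,Method 1,0.00,1.54,0.00
L-Leucine,amino_acid,Method 2,0.00,0.18,0.00
L-Leucine,amino_acid,Method 3,0.00,1.47,0.00
L-Leucine,amino_acid,Method 4,0.00,0.23,0.00
L-Leucine,amino_acid,Method 5,0.45,0.99,45.66
L-Tryptophan,amino_acid,Method 1,0.00,0.00,0.00
L-Tryptophan,amino_acid,Method 2,0.00,0.00,0.00
L-Tryptophan,amino_acid,Method 3,0.00,0.00,0.00
L-Tryptophan,amino_acid,Method 4,0.00,0.00,0.00
L-Tryptophan,amino_acid,Method 5,0.00,0.01,0.00
L-Tyrosine,amino_acid,Method 1,0.00,0.28,0.00
L-Tyrosine,amino_acid,Method 2,0.00,0.24,0.00
L-Tyrosine,amino_acid,Method 3,0.00,0.37,0.00
L-Tyrosine,amino_acid,Method 4,0.00,0.17,0.00
L-Tyrosine,amino_acid,Method 5,0.00,0.03,0.00
L-Phenylalanine,amino_acid,Method 1,0.00,0.53,0.00
L-Phenylalanine,amino_acid,Method 2,0.00,0.65,0.39
L-Phenylalanine,amino_acid,Method 3,0.09,0.78,11.94
L-Phenylalanine,amino_acid,Method 4,0.03,0.45,6.15
L-Phenylalanine,amino_acid,Method 5,0.21,0.24,86.55
Ascorbic acid,organic_acid,Method 1,0.00,0.02,0.00
Ascorbic acid,organic_acid,Method 2,0.00,0.04,0.00
Ascorbic acid,organic_acid,Method 3,0.00,0.09,0.00
Ascorbic acid,organic_acid,Method 4,0.00,0.01,0.00
Ascorbic acid,organic_acid,Method 5,0.09,0.11,86.49
Citric acid,organic_acid,Method 1,0.57,0.79,72.25
Citric acid,organic_acid,Method 2,1.02,1.24,82.56
Citric acid,organic_acid,Method 3,0.59,0.89,65.61
Citric acid,organic_acid,Method 4,0.90,0.69,130.81
Citric acid,organic_acid,Method 5,1.63,1.38,118.12
Succinic acid,organic_acid,Method 1,0.11,0.13,82.33
Succinic acid,organic_acid,Method 2,0.13,0.15,85.62
Succinic acid,organic_acid,Method 3,0.11,0.14,80.08
Succinic acid,organic_acid,Method 4,0.10,0.12,79.05
Succinic acid,organic_acid,Method 5,0.16,0.21,78.77
Palmitic acid,fatty_acid,Method 1,0.14,0.21,67.57
Palmitic acid,fatty_acid,Method 2,0.38,0.21,181.00
Palmitic acid,fatty_acid,Method 3,0.17,0.34,50.67
Palmitic acid,fatty_acid,Method 4,0.12,0.18,67.16
Palmitic acid,fatty_acid,Method 5,0.09,0.13,69.28
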