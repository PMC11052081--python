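well,substrate,category,replicate
A1,CONTROL,control,1
A2,beta-methyl-D-glucoside,carbohydrates,1
A3,D-galactonic acid gamma-lactone,carbohydrates,1
A4,L-arginine,amino_acids,1
A5,CONTROL,control,2
A6,beta-methyl-D-glucoside,carbohydrates,2
A7,D-galactonic acid gamma-lactone,carbohydrates,2
A8,L-arginine,amino_acids,2
A9,CONTROL,control,3
A10,beta-methyl-D-glucoside,carbohydrates,3
A11,D-galactonic acid gamma-lactone,carbohydrates,3
A12,L-arginine,amino_acids,3
B1,pyruvic acid methyl ester,carboxylic,1
B2,D-xylose,carbohydrates,1
B3,D-galacturonic acid,carboxylic,1
B4,L-asparagine,amino_acids,1
B5,pyruvic acid methyl ester,carboxylic,2
B6,D-xylose,carbohydrates,2
B7,D-galacturonic acid,carboxylic,2
B8,L-asparagine,amino_acids,2
B9,pyruvic acid methyl ester,carboxylic,3
B10,D-xylose,carbohydrates,3
B11,D-galacturonic acid,carboxylic,3
B12,L-asparagine,amino_acids,3
C1,Tween 40,polymers,1
C2,i-erythritol,carbohydrates,1
C3,2-hydroxybenzoic acid,phenolic,1
C4,L-phenylalanine,amino_acids,1
C5,Tween 40,polymers,2
C6,i-erythritol,carbohydrates,2
C7,2-hydroxybenzoic acid,phenolic,2
C8,L-phenylalanine,amino_acids,2
C9,Tween 40,polymers,3
C10,i-erythritol,carbohydrates,3
C11,2-hydroxybenzoic acid,phenolic,3
C12,L-phenylalanine,amino_acids,3
D1,Tween 80,polymers,1
D2,D-mannitol,carbohydrates,1
D3,4-hydroxybenzoic acid,phenolic,1
D4,L-serine,amino_acids,1
D5,Tween 80,polymers,2
D6,D-mannitol,carbohydrates,2
D7,4-hydroxybenzoic acid,phenolic,2
D8,L-serine,amino_acids,2
D9,Tween 80,polymers,3
D10,D-mannitol,carbohydrates,3
D11,4-hydroxybenzoic acid,phenolic,3
D12,L-serine,amino_acids,3
E1,alpha-cyclodextrin,polymers,1
E2,N-acetyl-D-glucosamine,carbohydrates,1
E3,gamma-hydroxybutyric acid,carboxylic,1
E4,L-threonine,amino_acids,1
E5,alpha-cyclodextrin,polymers,2
E6,N-acetyl-D-glucosamine,carbohydrates,2
E7,gamma-hydroxybutyric acid,carboxylic,2
E8,L-threonine,amino_acids,2
E9,alpha-cyclodextrin,polymers,3
E10,N-acetyl-D-glucosamine,carbohydrates,3
E11,gamma-hydroxybutyric acid,carboxylic,3
E12,L-threonine,amino_acids,3
F1,glycogen,polymers,1
F2,D-glucosaminic acid,carboxylic,1
F3,itaconic acid,carboxylic,1
F4,glycyl-L-glutamic acid,amino_acids,1
F5,glycogen,polymers,2
F6,D-glucosaminic acid,carboxylic,2
F7,itaconic acid,carboxylic,2
F8,glycyl-L-glutamic acid,amino_acids,2
F9,glycogen,polymers,3
F10,D-glucosaminic acid,carboxylic,3
F11,itaconic acid,carboxylic,3
F12,glycyl-L-glutamic acid,amino_acids,3
G1,D-cellobiose,carbohydrates,1
G2,glucose-1-phosphate,carbohydrates,1
G3,alpha-ketobutyric acid,carboxylic,1
G4,phenylethylamine,amines,1
G5,D-cellobiose,carbohydrates,2
G6,glucose-1-phosphate,carbohydrates,2
G7,alpha-ketobutyric acid,carboxylic,2
G8,phenylethylamine,amines,2
G9,D-cellobiose,carbohydrates,3
G10,glucose-1-phosphate,carbohydrates,3
G11,alpha-ketobutyric acid,carboxylic,3
G12,phenylethylamine,amines,3
H1,alpha-D-lactose,carbohydrates,1
H2,DL-alpha-glycerol phosphate,carbohydrates,1
H3,D-malic acid,carboxylic,1
H4,putrescine,amines,1
H5,alpha-D-lactose,carbohydrates,2
H6,DL-alpha-glycerol phosphate,carbohydrates,2
H7,D-malic acid,carboxylic,2
H8,putrescine,amines,2
H9,alpha-D-lactose,carbohydrates,3
H10,DL-alpha-glycerol phosphate,carbohydrates,3
H11,D-malic acid,carboxylic,3
H12,putrescine,amines,3
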