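code	parent	kind
MSE	MET	amino_acid
SEP	SER	amino_acid
TPO	THR	amino_acid
PTR	TYR	amino_acid
MLY	LYS	amino_acid
M3L	LYS	amino_acid
KCX	LYS	amino_acid
CSO	CYS	amino_acid
CME	CYS	amino_acid
OCS	CYS	amino_acid
HYP	PRO	amino_acid
MLE	LEU	amino_acid
FME	MET	amino_acid
PCA	GLU	amino_acid
SAC	SER	amino_acid
AIB	ALA	amino_acid
DAL	ALA	amino_acid
PSU	U	nucleotide
H2U	U	nucleotide
4SU	U	nucleotide
5MU	U	nucleotide
OMU	U	nucleotide
UR3	U	nucleotide
3AU	U	nucleotide
1MA	A	nucleotide
2MA	A	nucleotide
MA6	A	nucleotide
A2M	A	nucleotide
OMG	G	nucleotide
2MG	G	nucleotide
7MG	G	nucleotide
M2G	G	nucleotide
1MG	G	nucleotide
G7M	G	nucleotide
YG	G	nucleotide
OMC	C	nucleotide
5MC	C	nucleotide
4OC	C	nucleotide
CCC	C	nucleotide
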