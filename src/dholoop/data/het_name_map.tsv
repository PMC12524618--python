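# Chemical-component (het) codes -> controlled ligand vocabulary.
# Codes not listed here pass through unchanged (uppercased).
het_code	normalized_name
DOR	DHO
ORO	OROTIC_ACID
18Y	NCA
NCD	NCA
FOA	FOA
F6R	FOA
URF	5FU
5FU	5FU
5AU	5AU
AUR	5AU
PLH	PLUMBAGIN
HDD	HDDP
MLA	MALIC_ACID
MLT	MALIC_ACID
LMR	MALIC_ACID
ACY	ACY
ACT	ACY
CIT	CITRATE
FLC	CITRATE
CAC	CACODYLATE
IMD	IMIDAZOLE
LIG	LIG
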