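species	dhoase_type	loop_length	motif	residue_range	key_residue
S. cerevisiae	II	16	PAGVTTNSAAGVDPND	101-116	-
C. jejuni	II	16	PAGITTNSNGGVSSFD	-	-
E. coli	II	14	PANATTNSSHGVTS	105-118	-
S. enterica	II	14	PANATTNSSHGVTS	-	-
Y. pestis	II	14	PANATTNSTHGVSD	-	-
B. cenocepacia	II	14	PAGATTNSDHGVTD	-	-
V. cholerae	II	14	PAGATTNSDSGVTS	-	-
Human	III	12	LNETFSELRLDS	1559-1570	-
M. jannaschii	I	12	MVKSVGDLFIED	-	-
P. gingivalis	I	11	LGSSTGNMLVD	-	-
T. thermophilus	I	6	GRTNED	-	-
A. aeolicus	I	6	GSPVMD	-	GLY:148
S. aureus	I	6	GVGVQT	-	GLY:151
B. anthracis	I	6	GVGVQD	-	-
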