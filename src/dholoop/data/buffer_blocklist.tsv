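# Crystallization buffer / cryoprotectant het codes ignored by active-site
# ligand detection. Codes that Table 1 names as bona fide bound ligands
# (ACY/ACT, CAC, CIT/FLC, IMD) are deliberately NOT listed here.
het_code
GOL
EDO
PEG
PG4
1PE
P6G
SO4
PO4
NO3
CL
NA
K
BR
IOD
MPD
DMS
TRS
EPE
MES
BME
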