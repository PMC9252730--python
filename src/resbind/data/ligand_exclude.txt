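# HET codes never treated as biologically relevant ligands: water, cryo-protectants,
# buffer components and common counter-ions. One code per line; '#' starts a comment.
HOH
DOD
WAT
GOL
EDO
PEG
PGE
PG4
MPD
DMS
ACT
FMT
SO4
PO4
NO3
CO3
BCT
CL
BR
IOD
F
NA
K
CS
NH4
TRS
EPE
MES
BME
IMD
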