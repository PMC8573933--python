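# NDD genes not expressed in adult brain (median TPM < 1.5)
STRA6
ARSE
TM4SF20
SLC6A19
CA5A
GSX2
ZBTB20
NEUROG1
SCN10A
KPNA7
AGMO
HIST1H4C
TAT
RNU4ATAC
RMRP
IGF1
ASPM
GLI2
WDR62
ORC1
KIF4A
UPB1
HOXA1
CENPF
KIF14
TWIST1
STIL
FOXP2
KIF11
CEP55
CENPE
GATA6
SIK1
PLK4
FANCD2
MAT1A
BUB1B
HPD
HIST1H1E
CKAP2L
ESCO2
CCBE1
FAT4
OCLN
MIR17HG
ALG11
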