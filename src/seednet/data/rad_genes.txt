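ZCWPW1
TRIP4
SORCS1
OSTN
PLXNA4
SORCS2
CASP8
AKAP9
APP
ABCG1
TP53INP1
PFDN1
COBL
APOE
SORCS3
EPHA1
ACE
CR1
MAPT
KCNMB2
CLU
PDGFRL
PLD4
SORL1
CD2AP
GALNT7
SLC10A2
PILRA
CASS4
PLD3
MS4A6A
C1QTNF4
MS4A4A
ABI3
NCR2
UNC5C
PTK2B
MEF2C
ABCA7
LMX1B
TREM2
ECHDC3
BIN1
PSEN2
CD33
ZNF804B
PICALM
HLA-DRB5
PSEN1
INPP5D
TPBG
PLCG2
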