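gene	early	late
UNC5C	0.127	0.997
TP53INP1	0.093	0.931
ZCWPW1	0.156	0.979
ABCG1	0.192	0.956
PLD4	0.233	0.963
KCNMB2	0.954	0.269
ABCA7	0.831	0.180
CLU	0.822	0.235
TPBG	0.735	0.163
CASS4	0.202	0.774
SLC10A2	0.284	0.851
ECHDC3	0.951	0.396
INPP5D	0.363	0.874
AKAP9	0.647	0.195
SORL1	0.975	0.529
SORCS1	0.865	0.419
LMX1B	0.588	0.158
CASP8	0.425	0.851
OSTN	0.080	0.505
NCR2	0.492	0.888
SORCS3	0.482	0.864
PICALM	0.640	1.000
C1QTNF4	0.105	0.428
TRIP4	0.619	0.896
PSEN1	0.712	0.984
PSEN2	0.594	0.380
PILRA	0.489	0.289
ABI3	0.671	0.867
PLCG2	0.984	0.794
ACE	0.065	0.249
APOE	0.987	0.807
PTK2B	0.756	0.579
PDGFRL	0.111	0.272
SORCS2	0.481	0.641
MS4A6A	0.728	0.884
MS4A4A	0.881	0.727
TREM2	0.849	0.999
GALNT7	0.737	0.882
EPHA1	0.330	0.467
CD2AP	0.531	0.667
HLA-DRB5	0.847	0.948
COBL	0.830	0.740
PLXNA4	0.847	0.760
CR1	0.610	0.691
PLD3	0.584	0.647
MEF2C	0.800	0.739
PFDN1	0.596	0.657
ZNF804B	0.219	0.168
APP	0.676	0.705
BIN1	0.949	0.925
CD33	0.977	0.988
MAPT	0.534	0.526
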