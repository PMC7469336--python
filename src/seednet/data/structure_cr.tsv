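gene	brain_stem	cerebellum	cerebrum
ZCWPW1	0.991	0.080	0.783
TRIP4	0.997	0.226	0.772
SORCS1	0.076	0.602	0.807
OSTN	0.753	0.196	0.858
PLXNA4	0.182	0.601	0.854
SORCS2	0.785	0.136	0.605
CASP8	0.222	0.720	0.853
AKAP9	0.541	0.877	0.214
APP	0.505	0.990	0.376
ABCG1	0.392	0.325	0.897
TP53INP1	0.880	0.394	0.968
PFDN1	0.557	0.998	0.406
COBL	0.902	0.323	0.662
APOE	0.216	0.280	0.745
SORCS3	0.134	0.376	0.706
EPHA1	0.219	0.739	0.294
ACE	0.778	0.667	0.249
CR1	0.068	0.344	0.603
MAPT	0.337	0.542	0.863
KCNMB2	0.021	0.530	0.401
CLU	0.732	0.582	0.219
PDGFRL	0.634	0.395	0.126
PLD4	0.948	0.463	0.770
SORL1	0.935	0.462	0.612
CD2AP	0.351	0.691	0.772
GALNT7	0.390	0.823	0.699
SLC10A2	0.329	0.224	0.640
PILRA	0.601	0.896	0.494
CASS4	0.040	0.204	0.438
PLD3	0.536	0.355	0.752
MS4A6A	0.603	0.623	0.934
C1QTNF4	0.804	0.714	0.451
MS4A4A	0.728	0.499	0.859
ABI3	0.685	0.567	0.908
NCR2	0.776	0.664	0.975
UNC5C	0.797	0.517	0.765
PTK2B	0.688	0.979	0.899
MEF2C	0.812	0.695	0.986
ABCA7	0.082	0.338	0.095
LMX1B	0.003	0.078	0.276
TREM2	0.793	0.820	0.963
ECHDC3	0.805	0.703	0.670
BIN1	0.663	0.798	0.724
PSEN2	0.242	0.256	0.356
CD33	0.876	0.832	0.950
ZNF804B	0.073	0.141	0.162
PICALM	0.912	0.922	0.989
HLA-DRB5	0.973	0.910	0.986
PSEN1	0.879	0.924	0.866
INPP5D	0.937	0.987	0.982
TPBG	0.220	0.240	0.249
PLCG2	0.943	0.963	0.945
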