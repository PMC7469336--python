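gene	phenotype	z_gwas	z_network	z_combined	p_unadjusted	q_fdr
EPS8	DM	3.16	2.78	4.20	1.34E-05	8.77E-03
HSPA2	DA	2.98	1.51	3.17	7.51E-04	2.45E-01
ADAM10	DA	2.61	1.50	2.90	1.84E-03	4.01E-01
HSPA6	DA	2.13	1.63	2.66	3.88E-03	6.34E-01
CAMK2A	DM	0.94	2.60	2.50	6.13E-03	7.91E-01
HDAC1	DA,OS	1.40	1.97	2.38	8.55E-03	7.91E-01
MAPK10	DA,OS	1.58	1.68	2.30	1.06E-02	7.91E-01
CAT	DA,OS	2.31	0.89	2.27	1.17E-02	7.91E-01
FXR1	DM	0.58	2.60	2.24	1.24E-02	7.91E-01
CD164	DM	0.90	2.23	2.21	1.34E-02	7.91E-01
HSPB1	OS	1.58	1.52	2.19	1.43E-02	7.91E-01
FBXW7	OS	0.66	2.34	2.12	1.69E-02	7.91E-01
DAGLB	OS	1.52	1.48	2.12	1.71E-02	7.91E-01
NFE2L3	OS	1.71	1.20	2.06	1.98E-02	7.91E-01
MAFB	OS	1.56	1.31	2.03	2.11E-02	7.91E-01
ITGAX	DM	1.67	1.20	2.03	2.11E-02	7.91E-01
SETBP1	DA	1.26	1.60	2.02	2.14E-02	7.91E-01
ACHE	DM	2.12	0.71	2.00	2.28E-02	7.91E-01
ITGAM	DM	1.56	1.19	1.94	2.59E-02	7.91E-01
ITPR1	DA	1.01	1.72	1.93	2.68E-02	7.91E-01
HBB	OS	2.68	0.02	1.91	2.81E-02	7.91E-01
PLK3	DA	2.16	0.50	1.88	2.98E-02	7.91E-01
TRIB3	DM	1.35	1.29	1.87	3.08E-02	7.91E-01
RCAN1	DA,DM,OS	1.24	1.40	1.87	3.10E-02	7.91E-01
GABARAP	DM	0.74	1.87	1.85	3.23E-02	7.91E-01
NIPBL	DM	0.72	1.90	1.85	3.24E-02	7.91E-01
GPD1	OS	1.54	1.06	1.84	3.26E-02	7.91E-01
GRIN2A	DM	0.98	1.59	1.82	3.47E-02	8.10E-01
ITPKA	OS	0.57	1.95	1.78	3.78E-02	8.29E-01
DNM1	DM	1.02	1.46	1.76	3.94E-02	8.29E-01
PGC	DA	1.28	1.19	1.75	4.00E-02	8.29E-01
CIDEC	DM	1.60	0.87	1.74	4.06E-02	8.29E-01
TXNRD2	DA	1.85	0.59	1.73	4.21E-02	8.34E-01
BZW2	DM	1.60	0.80	1.69	4.51E-02	8.67E-01
CBX3	DA	1.54	0.81	1.66	4.81E-02	8.91E-01
PCNA	OS	2.31	0.03	1.65	4.91E-02	8.91E-01
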