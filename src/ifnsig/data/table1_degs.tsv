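gene	base_mean	log2fc	fdr	ifn_regulated	subset_high
S100A8	71.3	2.05	0.020	YES	YES
VCAN	48.7	1.85	0.0082	YES	YES
S100A9	150.5	1.84	0.029	YES	YES
CD163	9.5	1.81	0.020	YES	YES
SERPINA1	86.5	1.70	0.030	YES	YES
ANXA1	32.1	1.68	0.00042	YES	YES
PLAUR	10.9	1.67	0.044	YES	YES
CPVL	37.4	1.63	0.020	YES	YES
HK3	34.5	1.60	0.030	YES	YES
FCN1	186.6	1.59	0.048	YES	YES
CD36	21.8	1.56	0.030	YES	YES
TEKT4P2	53.7	1.50	0.024		YES
CST3	66.2	1.45	0.037	YES	YES
PYGL	16.4	1.43	0.049	YES	YES
USP18	52.3	0.61	0.029	YES
HDX	56.3	0.53	0.034	YES
RSAD2	117.5	0.50	0.029	YES
SLC30A1	199.0	0.39	0.042	YES
TIGAR	224.9	0.32	0.020
PLOD1	342.1	0.27	0.042	YES
HSPH1	2078.1	0.23	0.042
SLC27A4	416.9	0.21	0.049
CCNG1	1991.9	0.21	0.024	YES
P4HA1	1046.2	0.21	0.029
SKAP2	2309.0	0.20	0.029	YES
DNAJB6	2733.1	0.19	0.020	YES
DNAJA1	1903.0	0.19	0.029	YES
ANO6	1190.2	0.16	0.044
HEXB	891.3	0.15	0.024	YES
SNX6	1519.2	0.12	0.008	YES
URI1	2001.5	0.12	0.020
MCFD2	1951.9	0.11	0.041
YME1L1	3844.7	0.10	0.049	YES
lncRNA.1	46.2	-0.90	9.28E-06
MS4A4E	14.4	-0.87	0.039
LINC00865	189.3	-0.64	0.020
lncRNA.2	105.8	-0.62	0.00011
Lnc-GPA33-3	29.0	-0.46	0.018
EFEMP2	160.4	-0.41	0.026
lncRNA.3	72.0	-0.36	0.020
CCDC191	1752.9	-0.35	0.005
TEX22	82.3	-0.31	0.042
ZNF763	143.5	-0.29	0.021
LINC01089	1341.3	-0.28	0.00017
lncRNA.4	417.7	-0.26	0.029
PSMG3-AS1	549.5	-0.25	0.041
ICA1L	278.7	-0.22	0.030
Lnc-ZNF843-2	206.5	-0.22	0.029
SLC2A11	1536.6	-0.21	0.029	YES
MAGED1	1578.2	-0.21	0.029	YES
TMEM175	2896.4	-0.19	0.018
UNKL	2286.7	-0.18	0.018	YES
ASPSCR1	1110.6	-0.18	0.034
PPP1R3E	2514.3	-0.18	0.029	YES
RABL2A	1107.5	-0.18	0.030
TMEM198B	1411.5	-0.17	0.041	YES
L3MBTL1	1091.9	-0.16	0.041	YES
NSUN5P2	2665.0	-0.15	0.024	YES
GS1-124K5.11	1384.1	-0.15	0.042
B3GAT3	1829.3	-0.14	0.032
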