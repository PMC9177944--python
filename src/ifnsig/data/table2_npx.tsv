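protein	uniprot	ctl_npx	fm_npx	adjusted_p
STAMBP	O95630	4.09	4.76	0.010
AXIN1	O15169	2.09	3.12	0.010
SIRT2	Q8IXJ6	3.43	4.39	0.010
ST1A1	P50225	3.21	4.32	0.031
MMP-10	P09238	9.51	9.96	0.044
FGF-23	Q9GZV9	1.64	1.83	0.044
IL-18R1	Q13478	8.82	9.17	0.044
TNFSF14	O43557	6.93	7.47	0.044
FGF-21	Q9NSA1	4.18	5.13	0.044
TNF	P01375	2.96	3.32	0.044
CD5	P06127	5.82	6.07	0.048
CD40	P25942	11.73	12.05	0.048
CCL3	P10147	6.53	6.99	0.048
IL-10RB	Q08334	6.54	6.76	0.048
FGF-19	O95750	8.78	9.51	0.048
TNFRSF9	Q07011	6.97	7.31	0.048
IL8	P10145	6.83	7.30	0.048
EN-RAGE	P80511	5.25	5.99	0.048
CSF-1	P09603	10.72	10.86	0.049
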