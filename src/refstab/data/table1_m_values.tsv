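experiment	Alu-Sq	TBP	HPRT1	YWHAZ	GAPDH	SDHA	HMBS	B2M	UBC	ACTB	RPL13A
A	0.61	0.60	0.93	0.69	0.64	0.61	0.79	1.11	0.87	0.99	1.20
B	0.47	0.50	0.29	0.39	0.63	0.56	0.53	0.28	0.45	0.31	0.88
C	0.37	0.34	0.65	0.38	0.41	0.70	1.04	0.61	0.77	0.52	0.84
D	0.42	0.28	0.52	0.27	0.30	0.34	0.65	0.70	0.29	0.58	0.48
E	0.48	0.58	0.77	1.11	0.46	0.47	0.54	0.85	0.64	1.35	0.90
F	0.33	0.32	0.32	0.45	0.56	0.65	0.39	0.84	1.29	1.48	1.07
G	0.59	0.80	0.61	0.56	1.10	0.88	0.83	0.99	1.98	1.42	1.66
H	0.15	0.15	0.16	0.19	0.41	0.31	0.29	0.22	0.27	0.33	0.21
I	0.62	0.64	0.75	0.98	0.59	0.63	0.55	0.82	0.67	0.57	1.35
J	0.22	0.34	0.38	0.27	0.26	0.46	0.22	0.51	0.28	0.41	0.54
K	0.08	0.14	0.12	0.08	0.08	0.10	0.13	0.10	0.17	0.12	0.11
L	0.14	0.38	0.32	0.12	0.08	0.20	0.09	0.10	0.25	0.45	0.28
M	0.06	0.26	0.25	0.14	0.08	0.11	0.08	0.29	0.18	0.23	0.21
N	0.14	0.41	0.46	0.33	0.30	0.13	0.13	0.43	0.36	0.51	0.39
O	0.38	0.33	0.40	0.11	0.12	0.16	0.36	0.21	0.26	0.30	0.13
P	0.05	0.22	0.12	0.07	0.04	0.04	0.06	0.15	0.10	0.26	0.17
Q	0.16	0.47	0.27	0.14	0.14	0.21	0.18	0.23	0.25	0.28	0.30
R	0.75	0.90	0.59	1.18	0.81	0.54	0.86	0.53	0.98	0.93	1.06
S	0.68	1.15	0.86	0.61	0.77	0.63	1.22	0.62	1.01	0.94	1.08
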