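aa	mw_sidechain	vdw_volume	asa_total	asa_polar	polarizability	electronegativity	hbond_donors	hbond_acceptors	charge_pos	charge_neg	hyd_kyte_doolittle	hyd_hopp_woods	hyd_eisenberg	hyd_janin	hyd_rose_buried	hyd_engelman_ges	hyd_fauchere_pliska
A	15.0	67	115	0	0.05	2.50	0	0	0	0	1.8	-0.5	0.62	0.3	0.74	1.6	0.31
R	100.1	148	225	107	0.29	3.10	5	0	1	0	-4.5	3.0	-2.53	-1.4	0.64	-12.3	-1.01
N	58.1	96	160	101	0.13	3.05	2	2	0	0	-3.5	0.2	-0.78	-0.5	0.63	-4.8	-0.60
D	59.0	91	150	89	0.11	3.20	1	4	0	1	-3.5	3.0	-0.90	-0.6	0.62	-9.2	-0.77
C	47.1	86	135	39	0.13	2.60	1	0	0	0	2.5	-1.0	0.29	0.9	0.91	2.0	1.54
Q	72.1	114	180	98	0.18	3.00	2	2	0	0	-3.5	0.2	-0.85	-0.7	0.62	-4.1	-0.22
E	73.0	109	190	87	0.15	3.15	1	4	0	1	-3.5	3.0	-0.74	-0.7	0.62	-8.2	-0.64
G	1.0	48	75	0	0.00	2.45	0	0	0	0	-0.4	0.0	0.48	0.3	0.72	1.0	0.00
H	81.1	118	195	60	0.23	2.95	1	1	0	0	-3.2	-0.5	-0.40	-0.1	0.78	-3.0	0.13
I	57.1	124	175	0	0.19	2.45	0	0	0	0	4.5	-1.8	1.38	0.7	0.88	3.1	1.80
L	57.1	124	170	0	0.19	2.45	0	0	0	0	3.8	-1.8	1.06	0.5	0.85	2.8	1.70
K	72.1	135	200	48	0.22	2.90	2	0	1	0	-3.9	3.0	-1.50	-1.8	0.52	-8.8	-0.99
M	75.1	124	185	43	0.22	2.55	0	0	0	0	1.9	-1.3	0.64	0.4	0.85	3.4	1.23
F	91.1	135	210	0	0.29	2.50	0	0	0	0	2.8	-2.5	1.19	0.5	0.88	3.7	1.79
P	41.1	90	145	0	0.13	2.55	0	0	0	0	-1.6	0.0	0.12	-0.3	0.64	-0.2	0.72
S	31.0	73	115	42	0.06	2.95	1	1	0	0	-0.8	0.3	-0.18	-0.1	0.66	0.6	-0.04
T	45.0	93	140	42	0.11	2.90	1	1	0	0	-0.7	-0.4	-0.05	-0.2	0.70	1.2	0.26
W	130.2	163	255	27	0.41	2.70	1	0	0	0	-0.9	-3.4	0.81	0.3	0.85	1.9	2.25
Y	107.1	141	230	48	0.30	2.85	1	1	0	0	-1.3	-2.3	0.26	-0.4	0.76	-0.7	0.96
V	43.1	105	155	0	0.14	2.45	0	0	0	0	4.2	-1.5	1.08	0.6	0.86	2.6	1.22
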