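symbol	wt_ifng	wt_lps	signal_integration	wt_combo	ko_ifng	ko_lps	ko_combo	stat_nfkb	irf_nfkb	isre	stat	nfkb	cluster
Cxcl9	150.73	20.25	15.46	2643.50	0.93	9.87	9.52	x	-	-	-	-	A
Cxcl10	343.62	665.68	2.25	2273.44	0.47	119.63	66.53	x	x	-	-	-	A
Rsad2	22.91	209.45	2.19	509.05	1.53	2.93	2.71	-	-	X	x	x	A
Gbp5	53.48	82.66	2.85	388.28	1.28	65.64	72.68	x	-	X	x	x	A
Batf2	134.37	3.23	2.29	314.46	5.35	5.10	8.31	x	-	X	x	x	B
Ubd	21.54	3.38	13.11	326.57	0.80	4.71	6.44	x	-	X	-	-	B
Cd74	37.66	2.93	5.09	206.50	0.78	8.01	8.24	x	x	-	-	-	B
Fam26f	43.02	13.60	2.42	137.16	0.95	13.25	13.07	-	-	X	x	-	B
Serpina3g	24.76	13.36	2.59	98.56	2.12	5.12	7.79	x	-	X	-	-	B
Ccl5	2.14	249.59	2.04	512.54	0.83	64.48	52.22	x	x	-	-	-	C
Tnfaip2	6.52	45.55	2.27	118.00	1.14	28.83	27.04	x	-	-	-	-	C
Cd40	1.03	15.21	7.83	127.14	0.70	14.09	14.14	-	-	X	x	x	C
Lincr	1.07	21.38	4.84	108.75	1.16	29.33	25.78	-	-	X	x	x	C
Nos2	0.71	33.99	2.08	72.15	0.73	22.52	24.13	x	x	-	-	-	C
Ccrl2	4.18	8.16	3.72	45.93	0.76	5.87	4.65	x	-	X	-	-	D
Mx1	3.10	12.73	2.49	39.41	0.91	1.68	1.18	x	-	X	-	-	D
Has1	1.40	8.71	2.16	21.84	1.17	11.64	14.92	-	-	-	x	x	D
Oasl1	1.80	7.61	2.13	20.10	1.03	1.45	1.83	-	-	X	-	x	D
MCP-2	6.12	3.75	3.83	37.77	5.21	44.53	58.31	-	-	-	x	-	D
Atf3	3.73	2.47	3.27	20.29	1.21	4.34	3.96	-	-	-	x	x	D
Ifi205	5.39	2.99	2.28	19.10	0.64	4.24	4.81	-	-	X	x	-	D
Upp1	2.67	2.37	2.87	14.45	1.17	2.25	3.53	x	-	X	-	-	D
Tnfrsf11a	0.20	5.87	2.12	12.85	1.46	7.44	12.33	x	-	-	-	-	D
Irf8	6.13	0.41	2.98	19.51	1.40	1.03	0.77	x	-	-	-	-	E
MCP-5	1.05	0.32	8.65	11.86	0.69	0.59	0.78	-	-	x	x	x	E
Sectm1a	1.21	0.27	2.45	3.62	0.30	0.37	1.16	x	-	x	-	-	E
Gja4	1.25	0.83	4.50	9.35	0.55	0.37	0.27	-	-	-	-	x	E
Egr2	1.74	1.96	1.98	7.32	0.98	2.31	1.73	x	-	-	-	-	E
Itpk1	1.12	1.29	2.19	5.29	0.86	0.97	1.30	-	-	-	x	x	E
Etsrp71	0.48	0.83	2.43	3.18	1.39	0.96	0.96	-	-	-	x	x	E
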