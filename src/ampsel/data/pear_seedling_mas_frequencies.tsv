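sample_id	marker	total_reads	marker_reads	allele1	freq1	allele2	freq2	allele3	freq3	allele4	freq4	target_frequency	evaluation
Tsukuba 60	TsuENH157.mod	10597	3016	127	0.48	129	0.39	125	0.08	131	0.02	0.48	Resistant
592-021	TsuENH157.mod	9283	2859	129	0.45	131	0.40	127	0.09	133	0.03	0.09	Susceptible
Seedling 1	TsuENH157.mod	11028	2938	129	0.80	127	0.13	131	0.03	125	0.02	0.13	Susceptible
Seedling 2	TsuENH157.mod	11368	3574	129	0.48	131	0.36	127	0.10	133	0.02	0.10	Susceptible
Seedling 3	TsuENH157.mod	5786	1516	127	0.41	131	0.38	129	0.10	125	0.07	0.41	Resistant
Seedling 4	TsuENH157.mod	11885	3314	127	0.44	131	0.37	129	0.09	125	0.06	0.44	Resistant
Seedling 5	TsuENH157.mod	13207	3602	127	0.47	129	0.42	125	0.07	131	0.02	0.47	Resistant
Seedling 6	TsuENH157.mod	11114	2857	127	0.47	129	0.42	125	0.08	131	0.02	0.47	Resistant
Seedling 7	TsuENH157.mod	10381	2712	127	0.49	129	0.39	125	0.08	131	0.01	0.49	Resistant
Seedling 8	TsuENH157.mod	14526	4513	129	0.49	131	0.39	127	0.08	133	0.02	0.08	Susceptible
Seedling 9	TsuENH157.mod	9231	2253	127	0.36	131	0.28	129	0.19	125	0.07	0.36	Resistant
Seedling 10	TsuENH157.mod	6214	1456	127	0.39	131	0.38	129	0.11	125	0.05	0.39	Resistant
Tsukuba 60	PPACS2	10597	2025	114	0.56	132	0.31	130	0.08	128	0.02	0.31	Early harvesting
592-021	PPACS2	9283	2299	114	0.98	113	0.01	112	0.01	116	0.00	0.00	Late harvesting
Seedling 1	PPACS2	11028	2149	114	0.98	113	0.01	112	0.01	115	0.00	0.00	Late harvesting
Seedling 2	PPACS2	11368	2550	114	0.57	132	0.28	130	0.09	113	0.02	0.28	Early harvesting
Seedling 3	PPACS2	5786	1061	114	0.98	113	0.01	112	0.01	116	0.00	0.00	Late harvesting
Seedling 4	PPACS2	11885	2506	114	0.98	113	0.01	112	0.00	116	0.00	0.00	Late harvesting
Seedling 5	PPACS2	13207	2675	114	0.98	113	0.01	112	0.00	116	0.00	0.00	Late harvesting
Seedling 6	PPACS2	11114	2018	114	0.97	113	0.01	112	0.01	116	0.00	0.00	Late harvesting
Seedling 7	PPACS2	10381	1673	114	0.59	132	0.28	130	0.07	134	0.02	0.28	Early harvesting
Seedling 8	PPACS2	14526	3340	114	0.56	132	0.31	130	0.08	128	0.02	0.31	Early harvesting
Seedling 9	PPACS2	9231	1874	114	0.81	113	0.08	132	0.05	130	0.02	0.05	Late harvesting
Seedling 10	PPACS2	6214	980	114	0.93	113	0.03	132	0.02	112	0.01	0.02	Late harvesting
Tsukuba 60	Psc07	10597	1306	141	0.29	151	0.17	139	0.13	149	0.12	0.17	Red
592-021	Psc07	9283	1819	119	0.42	133	0.27	131	0.13	117	0.07	0.00	Green
Seedling 1	Psc07	11028	1726	119	0.52	141	0.19	139	0.11	117	0.07	0.00	Green
Seedling 2	Psc07	11368	2080	119	0.49	141	0.20	139	0.10	117	0.07	0.00	Green
Seedling 3	Psc07	5786	766	133	0.38	141	0.19	131	0.13	139	0.11	0.00	Green
Seedling 4	Psc07	11885	1559	133	0.32	141	0.24	139	0.14	131	0.13	0.00	Green
Seedling 5	Psc07	13207	1784	133	0.31	141	0.25	131	0.14	139	0.12	0.00	Green
Seedling 6	Psc07	11114	1528	119	0.52	151	0.16	149	0.11	117	0.07	0.16	Red
Seedling 7	Psc07	10381	1268	133	0.32	151	0.17	131	0.15	149	0.12	0.17	Red
Seedling 8	Psc07	14526	2760	133	0.34	141	0.21	131	0.14	139	0.13	0.00	Green
Seedling 9	Psc07	9231	1277	133	0.22	141	0.18	139	0.11	131	0.11	0.00	Green
Seedling 10	Psc07	6214	670	119	0.48	141	0.21	139	0.10	117	0.08	0.00	Green
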