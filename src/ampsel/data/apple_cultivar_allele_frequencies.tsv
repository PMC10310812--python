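sample_id	ploidy	marker	total_reads	marker_reads	allele1	freq1	allele2	freq2	allele3	freq3	allele4	freq4	predicted_genotype
Indo	2	MdPG1.mod	5540	1566	108	0.49	114	0.45	111	0.02	107	0.01	108/114
Delicious	2	MdPG1.mod	5870	1522	105	0.48	114	0.47	111	0.02	113	0.01	105/114
Fuji	2	MdPG1.mod	6603	1712	105	0.50	108	0.47	104	0.01	107	0.01	105/108
Gold Rush	2	MdPG1.mod	4873	1435	105	0.52	108	0.46	107	0.01	104	0.01	105/108
Santaro	3	MdPG1.mod	7284	2053	108	0.34	105	0.33	114	0.29	111	0.01	105/108/114
Jonagold	3	MdPG1.mod	5384	1560	108	0.33	105	0.32	114	0.31	111	0.01	105/108/114
Hokuto	3	MdPG1.mod	4575	968	105	0.36	108	0.33	114	0.27	107	0.01	105/108/114
Mutsu	3	MdPG1.mod	8565	2233	108	0.65	114	0.30	105	0.02	107	0.02	108/108/114
Indo	2	Alt_indel	5540	696	159	0.57	162	0.41	174	0.01	158	0.00	159/162
Delicious	2	Alt_indel	5870	961	159	0.53	162	0.44	174	0.01	158	0.01	159/162
Fuji	2	Alt_indel	6603	1018	162	0.99	161	0.01	NA	NA	NA	NA	162/162
Gold Rush	2	Alt_indel	4873	415	162	0.99	161	0.01	163	0.00	NA	NA	162/162
Santaro	3	Alt_indel	7284	772	162	0.99	161	0.01	NA	NA	NA	NA	162/162/162
Jonagold	3	Alt_indel	5384	520	162	0.99	161	0.01	159	0.00	NA	NA	162/162/162
Hokuto	3	Alt_indel	4575	761	162	0.63	159	0.35	161	0.01	147	0.00	159/162/162
Mutsu	3	Alt_indel	8565	976	162	0.98	161	0.02	160	0.00	NA	NA	162/162/162
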