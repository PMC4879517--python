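chrom	pos	design_family	mean_depth	cv	missing_individuals	set1_p	set1_r2	set1_maf	set2_p	set2_r2	set2_maf
chr14	26205721	HC	65	38	2	1.56E-02	0.1050	0.20	1.56E-05	0.1940	0.27
chr14	26954543	HC	207	40	0	9.23E-03	0.1174	0.27	2.24E-03	0.1309	0.47
chr14	27052970	HC	1	0	380	NaN	0	0.00	NaN	0	0.00
chr14	27118778	HC	52	21	1	3.72E-03	0.1054	0.18	1.13E-07	0.2776	0.26
chr14	27263681	HC	232	5	2	2.42E-03	0.1148	0.19	1.45E-08	0.3101	0.26
chr14	27742679	HC	244	2	1	1.34E-03	0.1274	0.18	2.14E-08	0.3041	0.27
chr14	28408093	HC	248	2	0	6.12E-04	0.1440	0.19	3.82E-06	0.2165	0.27
chr14	28415565	HC	248	2	0	6.12E-04	0.1440	0.19	9.53E-06	0.2007	0.26
chr14	28448817	HC	51	48	42	3.78E-03	0.1399	0.34	1.05E-02	0.1205	0.37
chr14	28686983	HC	248	2	0	8.90E-03	0.0866	0.20	8.29E-06	0.2031	0.27
chr14	28791319	HC	50	38	2	1.32E-02	0.1089	0.25	6.44E-05	0.2010	0.34
chr14	28824733	HC	101	49	2	1.32E-02	0.0782	0.20	4.53E-05	0.1749	0.28
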