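chrom	pos	design_family	mean_depth	cv	missing_individuals	pooled_p	pooled_r2	pooled_maf	hi_p	hi_r2	hi_maf	vr_p	vr_r2	vr_maf
chr3	14851567	HI	250	0	0	1.07E-16	0.3370	0.33	7.36E-06	0.2586	0.42	4.90E-13	0.4147	0.25
chr3	15171738	HI	247	2	0	2.05E-17	0.3491	0.28	7.31E-06	0.2587	0.30	5.33E-13	0.4137	0.25
chr3	15828002	HI	250	0	127	1.76E-10	0.3102	0.47	8.82E-03	0.1724	0.44	8.35E-09	0.4214	0.50
chr3	16007996	HI	245	3	0	1.26E-16	0.3357	0.26	5.35E-06	0.2646	0.26	4.10E-12	0.3892	0.26
chr3	16008017	HI	244	3	0	1.26E-16	0.3357	0.26	5.35E-06	0.2646	0.26	4.10E-12	0.3892	0.26
chr3	16162132	HI	250	0	67	2.70E-03	0.0763	0.31	2.73E-04	0.2502	0.43	3.78E-02	0.0710	0.21
chr3	16163517	HI	249	1	0	3.64E-17	0.3265	0.24	1.15E-06	0.2574	0.22	4.10E-12	0.3892	0.26
chr3	16246446	HI	241	5	0	5.22E-03	0.0425	0.05	6.13E-02	0.0431	0.06	5.29E-02	0.0377	0.05
chr3	16375440	HI	249	1	0	3.64E-17	0.3265	0.24	1.15E-06	0.2574	0.22	4.10E-12	0.3892	0.26
chr3	16402674	HI	113	39	1	1.61E-06	0.1385	0.42	6.88E-06	0.2599	0.35	1.35E-04	0.1678	0.50
chr3	16402706	HI	14	6	2	2.15E-15	0.3143	0.33	7.62E-06	0.2580	0.29	1.59E-10	0.3720	0.37
chr3	16473116	HI	249	1	0	1.67E-16	0.3336	0.43	2.06E-05	0.2391	0.36	1.86E-11	0.3992	0.49
chr3	16516083	HI	4	4	200	1.80E-05	0.2417	0.35	8.50E-04	0.2507	0.46	NaN	0	0.01
chr3	16520617	HI	249	1	0	8.04E-17	0.3390	0.24	1.15E-06	0.2574	0.23	4.78E-12	0.4158	0.26
chr3	16523313	HI	73	53	3	1.85E-16	0.3329	0.30	1.15E-06	0.2574	0.22	6.12E-11	0.3842	0.38
chr3	16774466	HI	249	1	0	1.06E-17	0.3356	0.26	1.26E-06	0.2557	0.29	5.02E-13	0.4145	0.24
chr3	16873018	HI	248	2	0	NaN	0	0.00	NaN	0	0.01	NaN	0	0.00
chr3	16873164	HI	88	46	0	1.06E-17	0.3356	0.26	1.26E-06	0.2557	0.28	5.02E-13	0.4145	0.24
chr3	17225240	HI	20	27	2	9.37E-14	0.2861	0.22	6.59E-05	0.2163	0.18	2.53E-10	0.3393	0.27
chr3	17225412	HI	149	0	31	8.45E-03	0.0413	0.06	2.17E-02	0.0720	0.06	1.06E-01	0.0281	0.06
chr3	17225585	HI	210	14	0	2.28E-17	0.3483	0.49	6.66E-07	0.3024	0.45	1.96E-11	0.3985	0.48
chr3	17774559	HI	62	151	124	1.97E-02	0.0649	0.31	1.08E-02	0.1319	0.22	4.35E-01	0.0328	0.44
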