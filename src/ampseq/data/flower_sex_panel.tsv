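chrom	pos	design_family	mean_depth	cv	missing_individuals	pooled_p	pooled_r2	pooled_maf	hi_p	hi_r2	hi_maf	hc_p	hc_r2	hc_maf	cc_p	cc_r2	cc_maf	mn_p	mn_r2	mn_maf
chr2	4245542	CC	248	1	0	1.64E-98	0.8238	0.27	1.92E-33	0.8204	0.31	2.32E-27	0.7714	0.24	2.99E-40	0.8696	0.24	NaN	0	0.08
chr2	4422069	CC	13	6	4	1.65E-13	0.1938	0.08	1.18E-03	0.1197	0.04	3.10E-05	0.1961	0.08	2.34E-06	0.2295	0.11	NaN	0	0
chr2	4428879	HI	109	42	1	7.18E-16	0.2256	0.10	4.57E-57	0.9517	0.30	NaN	0	0	NaN	0	0	NaN	0	0.08
chr2	4448335	HI	6	3	14	3.35E-06	0.0967	0.06	1.33E-06	0.2782	0.17	NaN	0	0	3.59E-01	0.0099	0.01	3.57E-01	0.0207	0.15
chr2	4457222	HI	248	2	0	1.66E-16	0.2336	0.10	2.96E-58	0.9531	0.29	NaN	0	0	NaN	0	0	4.54E-07	0.4852	0.48
chr2	4560461	HI	9	11	16	5.07E-146	0.9363	0.29	4.53E-49	0.9486	0.25	1.19E-32	0.8555	0.31	0.00E+00	1	0.29	1.29E-01	0.0505	0.01
chr2	4726521	HC	248	2	0	6.34E-17	0.2392	0.10	0.00E+00	1	0.29	NaN	0	0	NaN	0	0	5.23E-16	0.7711	0.25
chr2	4726692	HI	248	2	0	3.43E-173	0.9540	0.23	0.00E+00	1	0.20	7.68E-36	0.8595	0.24	0.00E+00	1	0.26	NaN	0	0
chr2	4798009	HI	96	49	1	8.30E-17	0.2385	0.10	0.00E+00	1	0.29	NaN	0	0	NaN	0	0	3.55E-01	0.0191	0.21
chr2	5005636	HI	248	1	0	5.52E-16	0.2264	0.10	4.58E-58	0.9526	0.30	NaN	0	0	NaN	0	0	5.23E-16	0.7711	0.25
chr2	5064267	MN	248	1	0	5.23E-16	0.7711	0.25	NaN	0	0.49	NaN	0	0.48	3.23E-01	0.0112	0.24	5.23E-16	0.7711	0.25
chr2	5068641	HI	249	1	0	6.34E-17	0.2392	0.39	0.00E+00	1	0.20	NaN	0	0.48	NaN	0	0.50	NaN	0	0
chr2	5181254	MN	132	51	8	6.74E-14	0.2170	0.19	9.09E-41	0.9002	0.47	5.44E-01	0.0159	0.06	NaN	0	0	NaN	0	0.04
chr2	5207140	HI	7	5	25	3.47E-106	0.8712	0.26	1.76E-39	0.8985	0.21	2.59E-28	0.8414	0.29	1.54E-37	0.8671	0.27	NaN	0	0
chr2	5219708	HI	248	1	0	1.66E-16	0.2336	0.39	2.96E-58	0.9531	0.20	NaN	0	0.48	NaN	0	0.50	4.54E-07	0.4852	0.47
chr2	5219969	CC	248	1	0	3.38E-145	0.9239	0.23	2.96E-58	0.9531	0.20	7.68E-36	0.8595	0.24	9.85E-61	0.9559	0.26	NaN	0	0
chr2	5220041	HI	248	1	0	1.66E-16	0.2336	0.10	2.96E-58	0.9531	0.29	NaN	0	0	NaN	0	0	4.64E-04	0.2945	0.47
chr2	5233638	HI	181	68	107	1.20E-01	0.0257	0.06	5.79E-03	0.1554	0.02	6.22E-01	0.0373	0.18	2.34E-01	0.0196	0.03	NaN	0	0
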