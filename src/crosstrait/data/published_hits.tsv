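snp	ea	oa	beta_exposure	p_exposure	beta_outcome	p_outcome	p_pleio	cytoband	pph4	reported_novel	single_variant_credible_set
rs7528419	A	G	-0.02	1.35e-16	-0.01	3.60e-9	1.53e-29	1p13.3	0.992	0	0
rs1892419	T	C	-0.01	2.66e-9	0.01	2.40e-6	8.09e-16	1p34.2	<0.001	0	0
rs7554349	C	G	0.01	2.91e-6	0.02	4.10e-8	6.71e-14	1q43	0.008	0	0
rs7585120	C	T	-0.01	1.64e-8	-0.02	2.30e-12	7.47e-30	2q14.1-2q14.2	<0.001	0	0
rs62165280	G	A	-0.01	4.39e-7	-0.03	2.60e-24	8.31e-51	2q14.2	<0.001	0	0
rs6002323	T	C	0.01	1.15e-6	-0.01	2.70e-10	1.02e-18	2q14.2	<0.001	0	0
rs111873781	C	T	-0.02	6.83e-9	-0.01	5.20e-6	4.80e-15	3p21.31	<0.001	0	0
rs3774751	G	T	0.01	4.42e-7	0.02	5.50e-19	4.03e-35	3p21.31	<0.001	0	0
rs899631	G	T	0.01	7.41e-9	-0.02	2.70e-19	3.07e-40	4q12	0.898	0	0
rs7661844	C	T	-0.01	3.86e-6	0.01	9.80e-11	6.03e-23	4q21.3	0.005	0	0
rs1471251	A	T	0.01	4.03e-7	-0.02	1.20e-25	2.71e-56	4q21.3-4q22.1	<0.001	0	1
rs71607411	A	T	-0.01	1.56e-9	0.01	1.50e-6	6.38e-23	4q21.3-4q22.1	<0.001	0	0
rs10020067	C	A	0.01	9.86e-13	-0.01	3.50e-11	8.66e-32	4q22.1	<0.001	0	0
rs965807	G	T	-0.01	3.30e-6	-0.02	1.10e-16	2.45e-33	4q22.2-4q22.3	0.278	0	0
rs7746495	G	T	-0.01	4.34e-6	0.01	1.70e-9	1.01e-15	6q25.3	0.348	0	0
rs904018	T	C	0.01	9.34e-9	0.02	1.10e-22	6.37e-38	8p23.1	<0.001	0	0
rs13261622	C	T	0.01	4.68e-6	0.02	1.20e-13	2.05e-29	8p23.1	0.127	0	0
rs11776499	G	A	-0.01	1.80e-6	-0.02	1.10e-12	1.31e-20	8p23.1	0.091	0	0
rs2737252	G	A	-0.01	8.19e-6	-0.03	2.90e-55	8.69e-97	8p23.3	<0.001	0	0
rs17661353	G	A	-0.01	4.28e-6	0.01	1.90e-8	6.80e-15	8p23.3	<0.001	0	0
rs635634	C	T	0.02	8.82e-13	0.03	6.80e-24	1.07e-59	9q34.2	0.997	0	0
rs10767659	G	T	-0.01	2.14e-6	0.01	1.60e-8	1.08e-12	11p14.1	0.010	0	0
rs4597047	T	C	0.02	2.15e-8	-0.02	2.50e-8	1.09e-19	11p15.2	<0.001	0	0
rs61880664	A	G	0.02	7.23e-11	-0.03	2.40e-21	1.10e-44	11p15.2	<0.001	0	0
rs11023763	C	T	-0.02	5.85e-12	-0.01	6.70e-10	6.32e-22	11p15.2	<0.001	0	0
rs117363662	G	A	0.11	5.25e-54	-0.03	1.30e-6	3.16e-81	11p15.2	<0.001	0	0
rs72872035	A	C	0.06	1.37e-35	0.02	5.90e-6	2.23e-51	11p15.2	<0.001	0	0
rs1440715	A	G	0.01	1.74e-6	0.02	1.40e-10	5.24e-16	11p15.2	<0.001	0	0
rs1320210	G	A	0.01	7.26e-6	-0.01	3.10e-6	1.63e-14	11p15.2	<0.001	0	0
rs589030	G	C	0.01	1.02e-7	-0.01	5.30e-6	1.08e-16	11q13.1	0.106	0	0
rs11052759	G	A	-0.01	7.82e-9	0.01	3.60e-6	5.03e-12	12p11.1	0.122	0	0
rs11045856	T	G	-0.01	2.86e-9	0.01	2.20e-6	4.38e-17	12p12.2-12p12.1	0.975	0	0
rs4149056	T	C	0.02	9.00e-14	-0.02	5.90e-8	4.20e-30	12p12.2-12p12.1	0.975	0	0
rs4760401	A	G	-0.01	1.24e-6	-0.01	2.60e-6	7.28e-13	12q22	0.362	1	0
rs9324063	G	T	0.01	1.95e-6	-0.02	3.30e-18	1.97e-37	14q32.32-q32.33	<0.001	0	0
rs34411783	G	A	-0.01	5.05e-6	-0.02	8.20e-18	1.57e-37	14q32.32-q32.33	<0.001	0	0
rs861544	G	A	0.01	6.65e-7	0.01	3.40e-10	2.04e-21	14q32.33	<0.001	0	0
rs55696130	A	G	-0.01	4.84e-7	0.01	1.50e-7	1.29e-16	14q32.33	<0.001	0	0
rs56369308	T	C	0.02	2.29e-18	-0.01	3.00e-9	7.74e-38	15q22.31	<0.001	0	0
rs35733741	G	A	-0.01	2.53e-9	-0.01	9.10e-9	3.79e-19	16p11.2	0.063	0	0
rs8614	C	A	0.01	1.41e-7	0.01	3.30e-8	2.82e-17	17q11.2	<0.001	0	0
rs10454087	C	T	0.01	8.69e-10	-0.01	1.10e-9	4.92e-24	17q21.2	0.274	0	0
rs12150353	C	T	0.01	2.80e-6	-0.01	6.80e-6	9.04e-14	17q21.31	0.002	1	0
rs11665052	A	G	0.01	2.77e-8	-0.02	1.20e-9	1.34e-27	18q21.32	0.956	0	0
rs1077151	A	G	-0.01	6.73e-6	0.01	5.50e-8	5.98e-15	19p13.2	0.009	1	0
rs3810242	G	T	-0.01	5.39e-7	0.01	5.50e-7	1.16e-13	19q13.42	0.759	0	0
rs79873740	C	T	-0.02	2.37e-7	-0.02	2.90e-6	2.64e-14	20q13.33	0.935	1	0
rs13054331	G	A	0.01	2.84e-7	0.01	4.70e-6	3.49e-14	22q11.22-22q11.23	0.627	0	0
rs5770908	G	A	0.01	2.70e-8	0.02	7.10e-19	7.33e-29	22q13.33	0.928	0	0
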