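SNP	EA	OA	Beta	eaf	chr	pos	se	p val
rs10006833	C	T	−0.01561	0.209061	4	9,953,097	0.002521	6.22 × 10^−10
rs10734121	A	G	−0.02543	0.845295	11	89,656,239	0.002837	3.28 × 10^−19
rs10746147	G	A	−0.0224	0.926163	12	80,316,758	0.003927	1.20 × 10^−8
rs10835333	G	A	0.014555	0.349229	11	3,957,766	0.002161	1.68 × 10^−11
rs10844657	T	C	0.012373	0.339731	12	9,893,213	0.002168	1.18 × 10^−8
rs1086893	C	T	0.029865	0.343174	1	2.13 × 10^8	0.002162	2.41 × 10^−43
rs10883359	G	A	−0.01313	0.284616	10	1.01 × 10^8	0.002268	7.30 × 10^−9
rs10906375	G	A	−0.01249	0.300993	10	13,498,371	0.002234	2.29 × 10^−8
rs10927074	C	T	0.079216	0.892265	1	2.36 × 10^8	0.0033	3.00 × 10^−127
rs11097787	T	C	−0.0145	0.402632	4	1.03 × 10^8	0.002087	3.83 × 10^−12
rs7819602	G	C	0.016196	0.612901	8	10,726,842	0.002115	1.98 × 10^−14
rs7832357	G	A	−0.01543	0.342269	8	1.27 × 10^8	0.002158	8.90 × 10^−13
rs79140637	A	G	−0.02748	0.054158	2	65,084,123	0.004583	2.09 × 10^−9
rs8113682	G	T	−0.02161	0.747423	19	19,743,730	0.002364	6.41 × 10^−20
rs875740	A	C	−0.01794	0.665329	16	16,123,048	0.002172	1.52 × 10^−16
rs905670	A	G	−0.01431	0.350304	6	90,958,502	0.002142	2.49 × 10^−11
rs915125	T	C	−0.02925	0.281093	6	82,463,376	0.002288	2.18 × 10^−37
rs9274351	A	T	0.019736	0.196595	6	32,632,425	0.002822	2.79 × 10^−12
rs9376098	A	T	0.023167	0.349186	6	1.35 × 10^8	0.002147	4.15 × 10^−27
rs9928015	T	G	−0.01499	0.302009	16	57,570,561	0.002233	2.01 × 10^−11
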