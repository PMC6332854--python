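chrom	first_id	last_id	start_bp	end_bp	dist_bp	ld	SNP	SW3	SW5	SW7	SW9	SW11
1	rs43761056	rs137207255	6317864	6324488	6625	M		0.032	0.036
1	rs42493480	rs42493494	125981534	126011455	29922	M			0.031	0.034	0.038
3	rs109872503	rs110244139	7371235	7460489	89255	M	0.072	0.098	0.071	0.085	0.086	0.089
3	rs132795858	rs134534136	29474206	29610884	136679	S		0.038	0.049	0.051	0.051	0.050
3	rs132763845	rs109427593	90594180	90664268	70089	M				0.036	0.045
3	rs134111725	rs133976586	93949186	94067553	118368	S						0.040
4	rs43490295	rs43490295	1008553	1008553		N	0.028
4	rs137252969	rs43385178	24143662	24225606	81945	W			0.037
4	rs110513194	rs135604613	27834564	27894006	59443	S					0.042
5	rs136407209	rs110430223	7525121	7583435	58315	S			0.030
5	rs41587994	rs109349300	18434417	18465179	30763	S		0.036	0.034
8	rs133253155	rs135484797	92216117	92289515	73399	S		0.033	0.034	0.033
9	rs137367597	rs137367597	1116610	1116610		N	0.028
9	rs110938040	rs135589084	12339368	12406450	67083	M					0.048	0.053
9	rs136867942	rs135252570	21441424	21497606	56183	M					0.037
9	rs133390891	rs43600182	61168282	61197874	29593	S			0.037
9	rs110730224	rs109847831	66977872	67045614	67743	M		0.040	0.039	0.040	0.040
9	rs135160781	rs110936646	100716451	100721452	5002	S		0.034
10	rs137812088	rs133615734	20448593	20541764	93172	M	0.063	0.040	0.041	0.038	0.044	0.052
10	rs134006987	rs136312573	43692759	43726489	33731	S		0.033	0.031
11	rs109122230	rs41655045	5751331	5768629	17318	M		0.033
11	rs43755797	rs137032372	43129117	43135745	6629	M		0.032
11	rs136174419	rs42731923	50332078	50417494	85417	S	0.032	0.069
15	rs132639440	rs136091960	72439829	72470564	30736	M			0.036	0.040	0.051
17	rs110304377	rs42926409	70788438	70935589	147152	M		0.035	0.043	0.054	0.056
18	rs137081181	rs134146295	14849540	14991573	142034	S		0.039	0.041	0.043	0.043	0.045
24	rs135709192	rs136715705	47570379	47596815	26437	S		0.033	0.033	0.034	0.034	0.034
24	rs110779214	rs109148899	48585933	48632298	46366	S		0.038	0.038
25	rs136382747	rs135235176	55868854	55975740	106887	M				0.040
26	rs110607501	rs108984883	17590025	17598054	8030	S		0.033	0.034	0.034
28	rs133176306	rs109605337	19035737	19066768	31032	S		0.034	0.038
29	rs134774253	rs42146826	26876269	26885074	8806	S		0.033
29	rs136755211	rs42192064	43980089	44042363	62275	S			0.032	0.032
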