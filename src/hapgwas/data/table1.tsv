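marker	chrom	pos	allele1	freq1	effect1	se1	allele2	freq2	effect2	se2	variance	gene
rs109294639	3	7384182	T	0.094	-0.40	0.08	C	0.906	0.40	0.08	0.027	NOS1AP (intron1)
rs134499129	3	7390035	A	0.163	-0.51	0.06	G	0.837	0.51	0.06	0.072	NOS1AP (intron1)
rs41595711	3	7391544	T	0.185	-0.30	0.06	C	0.815	0.30	0.06	0.027	NOS1AP (intron1)
rs43490295	4	1008553	G	0.120	-0.37	0.07	A	0.880	0.37	0.07	0.028	-
rs137367597	9	1116610	C	0.135	-0.34	0.07	A	0.865	0.34	0.07	0.028	-
rs41623448	10	20486971	C	0.064	-0.73	0.09	T	0.936	0.73	0.09	0.063	near TBCD21
rs136174419	11	50332078	A	0.112	-0.37	0.07	G	0.888	0.37	0.07	0.028	near SUCLG1
rs42732955	11	50406682	A	0.124	-0.39	0.07	G	0.876	0.39	0.07	0.032	SUCLG1 (intron1)
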