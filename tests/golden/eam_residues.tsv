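# config_hash: e34848e8c1a5
residue	unit	kappa_f	dG_f	ddG_site5
1	1	8.248036	-1.250000	-1.500000
2	1	8.248036	-1.250000	-1.500000
3	1	8.248036	-1.250000	-1.500000
4	1	8.248036	-1.250000	-1.500000
5	1	8.248036	-1.250000	-1.500000
6	1	8.248036	-1.250000	-1.500000
7	1	8.248036	-1.250000	-1.500000
8	1	8.248036	-1.250000	-1.500000
9	2	8.248036	-1.250000	0.000000
10	2	8.248036	-1.250000	0.000000
11	2	8.248036	-1.250000	0.000000
12	2	8.248036	-1.250000	0.000000
13	2	8.248036	-1.250000	0.000000
14	2	8.248036	-1.250000	0.000000
15	2	8.248036	-1.250000	0.000000
16	2	8.248036	-1.250000	0.000000
17	3	8.248036	-1.250000	0.000000
18	3	8.248036	-1.250000	0.000000
19	3	8.248036	-1.250000	0.000000
20	3	8.248036	-1.250000	0.000000
21	3	8.248036	-1.250000	0.000000
22	3	8.248036	-1.250000	0.000000
23	3	8.248036	-1.250000	0.000000
24	3	8.248036	-1.250000	0.000000
25	4	8.248036	-1.250000	0.000000
26	4	8.248036	-1.250000	0.000000
27	4	8.248036	-1.250000	0.000000
28	4	8.248036	-1.250000	0.000000
29	4	8.248036	-1.250000	0.000000
30	4	8.248036	-1.250000	0.000000
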