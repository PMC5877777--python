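# config_hash: e34848e8c1a5
target	found	cost	path
3	1	0.104584	5-4-3
4	1	0.049708	5-4
5	1	0.000000	5
6	1	0.051563	5-6
7	1	0.101082	5-4-7
16	1	9.399039	5-27-24-14-17-16
17	1	8.781521	5-27-24-14-17
18	1	9.435541	5-27-24-14-17-18
19	1	10.123141	5-27-24-14-17-16-19
20	1	9.454497	5-27-24-14-17-20
24	1	1.551422	5-27-24
25	1	2.275877	5-27-28-25
26	1	1.502529	5-27-26
27	1	0.740912	5-27
28	1	1.489651	5-27-28
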