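# config_hash: e34848e8c1a5
	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24	25	26	27	28	29	30
dccm	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	1	1	1	1	1	0	0	0	1	1	1	1	1	0	0
eam	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
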