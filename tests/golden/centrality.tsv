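# config_hash: e34848e8c1a5
residue	BC_raw	BC_norm	L	unreachable_pairs
1	12.916866	0.031815	2.357874	0.000000
2	5.755647	0.014176	2.548966	0.000000
3	3.395201	0.008363	2.773966	0.000000
4	50.965817	0.125532	2.087241	0.000000
5	66.025469	0.162624	1.957356	0.000000
6	11.273866	0.027768	2.602126	0.000000
7	13.070313	0.032193	2.536092	0.000000
8	41.505964	0.102231	2.045690	0.000000
9	16.749575	0.041255	2.393218	0.000000
10	0.450468	0.001110	2.955517	0.000000
11	15.066718	0.037110	2.420747	0.000000
12	2.817441	0.006940	2.862931	0.000000
13	4.529276	0.011156	2.676207	0.000000
14	51.477612	0.126792	2.062759	0.000000
15	37.237167	0.091717	2.239425	0.000000
16	10.375990	0.025557	2.645977	0.000000
17	39.685498	0.097748	2.291609	0.000000
18	33.882758	0.083455	2.172471	0.000000
19	4.610616	0.011356	2.761494	0.000000
20	0.833364	0.002053	3.026839	0.000000
21	2.871335	0.007072	2.738448	0.000000
22	1.763895	0.004345	2.860862	0.000000
23	18.456255	0.045459	2.339540	0.000000
24	61.712383	0.152001	1.982471	0.000000
25	13.897841	0.034231	2.490575	0.000000
26	10.187506	0.025092	2.613448	0.000000
27	60.301933	0.148527	2.010862	0.000000
28	41.660083	0.102611	2.183103	0.000000
29	4.171628	0.010275	2.772471	0.000000
30	2.836515	0.006986	2.761092	0.000000
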