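# config_hash: e34848e8c1a5
res_i	res_j	correlation	cost	contact_freq
1	2	-0.008242	4.798548	0.783333
1	4	0.009577	4.648405	0.520000
1	11	-0.003419	5.678535	0.930000
2	3	-0.023249	3.761476	0.760000
2	5	-0.017530	4.043862	0.595000
3	4	0.946602	0.054877	0.998333
3	6	0.946703	0.054769	0.661667
4	5	0.951508	0.049708	1.000000
4	7	0.949923	0.051375	0.703333
5	6	0.949744	0.051563	1.000000
5	27	-0.476679	0.740912	0.866667
6	7	0.948976	0.052372	1.000000
7	8	0.007654	4.872504	0.768333
7	10	0.025801	3.657340	0.535000
8	9	-0.011730	4.445627	0.673333
8	18	-0.010523	4.554152	1.000000
9	10	-0.010701	4.537401	0.715000
11	12	-0.001548	6.470789	0.736667
11	14	-0.004412	5.423329	0.550000
12	13	-0.029472	3.524307	0.740000
12	15	-0.013681	4.291748	0.530000
13	14	0.000278	8.189603	0.735000
14	15	-0.002883	5.848922	0.695000
14	17	-0.016591	4.098920	0.543333
14	24	0.043666	3.131179	1.000000
15	16	-0.029370	3.527770	0.723333
15	18	0.015337	4.177462	0.535000
16	17	0.539282	0.617517	0.803333
16	19	0.484759	0.724102	0.628333
17	18	0.519951	0.654020	0.853333
17	20	0.510188	0.672976	0.578333
18	19	0.480239	0.733470	0.840000
19	20	0.475255	0.743904	0.846667
21	22	0.021080	3.859422	0.706667
21	24	0.037383	3.286533	0.550000
22	23	0.017098	4.068775	0.721667
22	25	0.022104	3.812012	0.528333
23	24	-0.000114	9.082091	0.765000
23	26	0.030129	3.502275	0.526667
24	25	0.448157	0.802611	0.845000
24	27	0.444632	0.810509	0.593333
25	26	0.449615	0.799363	0.798333
25	28	0.455561	0.786226	0.576667
26	27	0.466911	0.761617	0.820000
26	29	0.010205	4.584920	0.591667
27	28	0.472963	0.748739	0.848333
27	30	0.001017	6.891389	0.506667
28	29	-0.005893	5.134006	0.746667
29	30	-0.010257	4.579840	0.711667
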