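Code	Scientific Name	Clean Reads Number (M)	Q_20_ (%)	Homo SNPs	Hete SNPs	Total SNPs
A1	Ribes fasciculatum	7.68	98.06	18,169	264	18,433
A2	Ribes fasciculatum var. chinense	10.56	98.08	23,189	322	23,511
A3	Ribes fasciculatum var. chinense	14.26	98.01	25,609	577	26,186
B1	Ribes heterotrichum	6.22	98	30,028	554	30,582
B2	Ribes komarovii	17.2	97.89	33,558	797	34,355
B3	Ribes alpinum	8.38	97.96	26,143	832	26,975
B4	Ribes giraldii var. polyanthum	4.32	98.03	25,384	496	25,880
B5	Ribes pseudofasciculatum	0.7	97.98	4982	66	50,48
B6	Ribes takare var. desmocarpum	14.97	97.86	33,613	662	34,275
B7	Ribes kialanum	6.95	98.18	29,730	627	30,357
B8	Ribes tenue	9.34	97.82	25,164	523	25,687
B9	Ribes tenue	12.47	98.1	33,332	843	34,175
B10	Ribes laurifolium var. yunnanense	9.62	97.89	21,561	313	21,874
B11	Ribes laurifolium var. yunnanense	10.65	98.02	23,175	368	23,543
B12	Ribes hunanense	10.41	98.17	25,959	431	26,390
B13	Ribes laurifolium	6.96	98.02	18,367	243	18,610
B14	Ribes davidii	7.66	98.01	18,560	301	18,861
B15	Ribes davidii	9.76	97.97	23,034	605	23,639
C1	Ribes aciculare	10.83	97.84	127,633	14,111	141,744
C2	Ribes aciculare	9.97	97.94	126,955	12,425	139,380
C3	Ribes burejense	15.79	97.84	142,706	13,211	155,917
C4	Ribes stenocarpum	2.07	98.01	141,709	10,065	151,774
C5	Ribes stenocarpum	18.36	97.89	144,656	23,607	168,263
D1	Ribes fragrans	11.8	98.12	45,922	1578	47,500
D2	Ribes procumbens	19.07	98.07	38,844	2554	41,398
D3	Ribes nigrum	8.58	98.14	36,776	1009	37,785
D4	Ribes procumbens	12.39	98.14	42,188	1394	43,582
D5	Ribes nigrum	22.03	97.98	47,442	1601	49,043
E1	Ribes griffithii	8.52	98.18	40,367	849	41,216
F1	Ribes palczewskii	9.33	98.05	42,553	1036	43,589
F2	Ribes tenue	11.72	98.14	43,108	1399	44,507
F3	Ribes palczewskii	9.52	98.06	41,924	1114	43,038
F4	Ribes palczewskii	21.29	97.94	45,801	1590	47,391
F5	Ribes moupinense	7.57	98.16	40,291	805	41,096
F6	Ribes setchuense	12.04	97.87	42,788	1120	43,908
F7	Ribes setchuense	15.75	97.89	43,072	1100	44,172
F8	Ribes setchuense	14.1	97.94	44,005	1365	45,370
F9	Ribes setchuense	6.49	97.72	36,222	741	36,963
F10	Ribes mandshuricum	14.35	97.85	44,773	1078	45,851
F11	Ribes mandshuricum	15.01	98.16	45,074	988	46,062
F12	Ribes longiracemosum	9.85	98.07	36,479	631	37,110
F13	Ribes himalense	11.21	97.85	35,869	801	36,670
F14	Ribes himalense	6.02	98.03	39,633	834	40,467
F15	Ribes himalense	15.92	98.07	45,382	1185	46,567
F16	Ribes himalense	15.03	98.06	37,404	947	38,351
F17	Ribes atropurpureum	12.42	98	43,556	1244	44,800
F18	Ribes atropurpureum	13.9	98.06	44,863	1240	46,103
F19	Ribes atropurpureum	10.93	98.02	42,549	1254	43,803
F20	Ribes altissimum	6.96	98.14	34,220	721	34,941
F21	Ribes altissimum	14.78	97.73	42,454	1232	43,686
F22	Ribes altissimum	14.17	98.06	44,704	1276	45,980
F23	Ribes altissimum	14.48	98.07	43,845	1201	45,046
Average		11.35	98.00	45,314	2399	47,713
Total		590.36		2,335,324	116,130	2,451,454
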