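mirna	coordinates	log2_fc	pvalue	padj	direction
miR-1306-3p	chr22:20073635_20073652	1.05	7.52E-16	1.34E-12	down
miR-1286	chr22:20236668_20236688	1.79	2.89E-06	1.84E-03	down
miR-1306-5p	chr22:20073595_20073616	0.85	3.09E-06	1.84E-03	down
miR-185-5p	chr22:20020676_20020697	1.04	1.37E-05	6.11E-03	down
miR-3175	chr15:93447638_93447659	1.30	3.12E-05	1.12E-02	down
miR-3158-3p	chr10:103361184_103361205,chr10:103361223_103361244	0.80	9.97E-05	2.97E-02	down
miR-185-3p	chr22:20020711_20020732	1.06	1.49E-03	1.69E-01	down
miR-486-3p	chr8:41517961_41517981,chr8:41518004_41518024	1.24	1.51E-03	1.69E-01	down
miR-1249	chr22:45596839_45596860	0.86	2.96E-03	2.44E-01	down
miR-6840-5p	chr7:99954279_99954302	1.41	3.00E-03	2.44E-01	down
miR-491-5p	chr9:20716119_20716140	0.85	4.63E-03	2.67E-01	down
miR-4804-5p	chr5:72174427_72174447	1.20	5.88E-03	2.93E-01	down
miR-767-3p	chrX:151561919_151561941	1.08	6.32E-03	2.93E-01	down
miR-34b-3p	chr11:111383712_111383733	-1.52	5.81E-04	1.21E-01	up
miR-34c-5p	chr11:111384176_111384198	-1.33	6.29E-04	1.21E-01	up
miR-26b-5p	chr2:219267380_219267400	-0.74	6.75E-04	1.21E-01	up
miR-146b-3p	chr10:104196313_104196334	-1.28	8.59E-04	1.40E-01	up
miR-23a-5p	chr19:13947444_13947465	-1.38	9.86E-04	1.47E-01	up
miR-296-3p	chr20:57392681_57392702	-0.64	1.44E-03	1.69E-01	up
miR-4449	chr4:53578887_53578908	-1.46	2.14E-03	2.09E-01	up
miR-4792	chr3:24562903_24562920	-1.22	2.21E-03	2.09E-01	up
miR-148a-3p	chr7:25989542_25989563	-1.17	2.22E-03	2.09E-01	up
miR-320b	chr1:117214409_117214430,chr1:224444751_224444772	-0.63	2.90E-03	2.44E-01	up
miR-3609	chr7:98479323_98479346	-1.27	3.26E-03	2.54E-01	up
miR-320c	chr18:19263520_19263539,chr18:21901680_21901699	-0.86	3.52E-03	2.61E-01	up
miR-126-3p	chr9:139565105_139565126	-1.13	3.87E-03	2.61E-01	up
miR-320e	chr19:47212551_47212568	-1.05	3.94E-03	2.61E-01	up
miR-7704	chr2:177053571_177053589	-1.12	3.94E-03	2.61E-01	up
miR-181b-5p	chr1:198828054_198828076,chr9:127456004_127456026	-0.65	4.08E-03	2.61E-01	up
miR-146a-5p	chr5:159912379_159912400	-1.10	4.37E-03	2.66E-01	up
miR-6757-5p	chr12:53450733_53450754	-1.30	5.12E-03	2.86E-01	up
miR-4682	chr10:121718034_121718056	-1.32	5.59E-03	2.93E-01	up
miR-26a-5p	chr12:58218441_58218462,chr3:38010904_38010925	-0.81	6.08E-03	2.93E-01	up
miR-3195	chr20:60639868_60639884	-1.18	6.16E-03	2.93E-01	up
miR-126-5p	chr9:139565068_139565088	-0.94	6.31E-03	2.93E-01	up
miR-125a-5p	chr19:52196521_52196544	-0.91	6.39E-03	2.93E-01	up
miR-548q	chr10:12767324_12767345	-0.98	6.66E-03	2.98E-01	up
miR-320d	chr13:41301964_41301982,chrX:140008337_140008355	-0.94	7.37E-03	3.10E-01	up
miR-4497	chr12:110271155_110271171	-1.15	7.47E-03	3.10E-01	up
miR-27a-3p	chr19:13947261_13947281	-0.84	8.11E-03	3.17E-01	up
miR-455-5p	chr9:116971729_116971750	-0.70	8.25E-03	3.17E-01	up
miR-7113-5p	chr11:67800332_67800352	-0.81	8.33E-03	3.17E-01	up
miR-6842-5p	chr8:27290892_27290913	-1.25	8.64E-03	3.18E-01	up
miR-146b-5p	chr10:104196277_104196298	-1.07	8.70E-03	3.18E-01	up
miR-6852-5p	chr9:35710713_35710733	-0.88	9.21E-03	3.29E-01	up
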