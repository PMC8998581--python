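subgroup	rs_id	leap_id	log2fc
LEA1.1	Rs_164046	RsLEA86	6.97
LEA1.1	Rs_152347	RsLEA78	6.39
LEA1.1	Rs_185287	RsLEA104	5.24
LEA1.1	Rs_186228	RsLEA277	3.91
LEA1.1	Rs_116928	RsLEA44	3.74
LEA1.1	Rs_105968	RsLEA146	2.52
LEA1.1	Rs_125102	RsLEA52	2.45
LEA1.1	Rs_172584	RsLEA267	2.43
LEA1.1	Rs_183967	RsLEA101	2.35
LEA1.1	Rs_156613	RsLEA266	2.21
LEA1.3	Rs_170082	RsLEA129	3.00
LEA1.3	Rs_108065	RsLEA26	2.55
LEA2.0	Rs_130914	RsLEA122	-2.24
LEA2.1	Rs_169359	RsLEA232	2.93
LEA2.1	Rs_127322	RsLEA55	2.33
LEA2.2	Rs_151841	RsLEA154	4.64
LEA2.2	Rs_104785	RsLEA275	4.51
LEA2.2	Rs_125141	RsLEA276	3.66
LEA2.2	Rs_164865	RsLEA272	2.50
LEA2.2	Rs_187807	RsLEA125	2.07
LEA2.2	Rs_173883	RsLEA265	-2.98
LEA2.2	Rs_166384	RsLEA269	-4.06
LEA2.3	Rs_194495	RsLEA270	3.77
LEA2.3	Rs_110370	RsLEA262	3.19
LEA2.3	Rs_121097	RsLEA261	3.09
LEA2.3	Rs_118201	RsLEA230	2.44
LEA2.3	Rs_183071	RsLEA264	2.39
LEA2.3	Rs_193485	RsLEA291	-2.14
LEA2.3	Rs_171129	RsLEA256	-2.59
LEA2.3	Rs_138912	RsLEA296	-2.71
LEA2.3	Rs_145248	RsLEA285	-2.89
LEA2.3	Rs_180651	RsLEA98	-3.46
LEA2.3	Rs_138298	RsLEA68	-5.55
LEA2.4	Rs_110833	RsLEA254	-2.55
LEA2.4	Rs_181906	RsLEA257	-3.77
LEA2.5	Rs_160078	RsLEA228	8.12
LEA2.5	Rs_159852	RsLEA239	3.66
LEA2.5	Rs_162712	RsLEA211	3.34
LEA2.5	Rs_139255	RsLEA244	-2.32
LEA2.5	Rs_186090	RsLEA121	-3.49
LEA2.5	Rs_140027	RsLEA212	-3.75
LEA2.5	Rs_149607	RsLEA103	-4.03
LEA3.1	Rs_153025	RsLEA80	2.23
LEA3.1	Rs_125374	RsLEA53	-2.00
LEA3.1	Rs_161911	RsLEA85	-3.48
LEA3.2	Rs_114021	RsLEA128	-9.07
LEA4.2	Rs_146887	RsLEA75	6.42
LEA4.2	Rs_131921	RsLEA312	5.87
LEA4.2	Rs_194183	RsLEA188	4.99
LEA4.2	Rs_186681	RsLEA310	4.94
LEA4.2	Rs_148951	RsLEA76	3.10
LEA4.2	Rs_146172	RsLEA316	-4.35
LEA4.2	Rs_182435	RsLEA51	-4.91
LEA4.3	Rs_190897	RsLEA110	6.04
LEA4.3	Rs_189187	RsLEA109	5.64
LEA4.3	Rs_131918	RsLEA311	5.12
LEA4.3	Rs_109487	RsLEA175	4.90
LEA4.3	Rs_109602	RsLEA301	4.29
LEA4.3	Rs_184475	RsLEA309	3.77
LEA4.3	Rs_149505	RsLEA130	2.95
LEA4.3	Rs_181059	RsLEA302	2.74
LEA4.3	Rs_136891	RsLEA314	2.73
LEA4.3	Rs_190898	RsLEA111	2.31
LEA4.3	Rs_108999	RsLEA36	2.18
LEA4.3	Rs_166537	RsLEA49	1.99
LEA4.3	Rs_172003	RsLEA95	-3.63
LEA5	Rs_188268	RsLEA202	11.80
LEA5	Rs_159833	RsLEA196	8.53
LEA5	Rs_128109	RsLEA200	8.13
LEA5	Rs_193475	RsLEA204	8.04
LEA5	Rs_124807	RsLEA201	5.55
LEA5	Rs_125649	RsLEA199	4.35
LEA5	Rs_176248	RsLEA203	2.86
DEH1	Rs_131408	RsLEA166	3.78
DEH1	Rs_172145	RsLEA139	3.38
DEH1	Rs_134636	RsLEA298	3.09
DEH1	Rs_107019	RsLEA152	2.78
DEH1	Rs_181340	RsLEA151	2.50
DEH1	Rs_113392	RsLEA163	2.30
DEH2	Rs_156753	RsLEA172	4.35
SMP1	Rs_140935	RsLEA70	7.78
SMP1	Rs_106521	RsLEA33	3.67
SMP2	Rs_135719	RsLEA66	8.03
SMP2	Rs_134737	RsLEA65	3.22
SMP2	Rs_134736	RsLEA64	2.98
SMP2	Rs_156298	RsLEA83	2.45
SMP3	Rs_140941	RsLEA71	9.22
SMP3	Rs_106559	RsLEA34	5.99
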