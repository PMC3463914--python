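gene_id	name	basal	transitional	maturing	mature
GRMZM2G041980	ZmNIP1;1	284.4251	55.78293	1.32962	0.604141
GRMZM2G028325	ZmNIP2;1	0.738541	3.736517	108.7187	151.1207
GRMZM2G137108	ZmNIP2;2	12.83963	65.19496	110.8307	191.0704
GRMZM2G081239	ZmNIP2;3	1.390615	38.11073	19.33411	28.52731
GRMZM2G176209	ZmNIP3;1	10.89309	0.622895	0.379714	0.028008
GRMZM2G174807	ZmPIP1;1	1373.24	624.1622	551.3903	696.9544
GRMZM2G392975	ZmPIP1;3	320.3079	208.3987	120.4039	143.314
GRMZM2G392975	ZmPIP1;4	320.3079	208.3987	120.4039	143.314
GRMZM2G081843	ZmPIP1;5	6.403676	129.4154	92.4027	203.5336
GRMZM2G136032	ZmPIP1;6	8.864766	2.943776	5.884045	10.33727
GRMZM2G014914	ZmPIP2;1	863.1962	222.715	133.0945	270.8236
GRMZM2G092125	ZmPIP2;2	365.4722	72.14911	103.3769	246.2429
GRMZM2G081192	ZmPIP2;3	99.41061	97.24697	32.23512	64.3703
GRMZM2G154628	ZmPIP2;4	159.1274	254.0077	62.26854	66.46106
GRMZM2G178693	ZmPIP2;5	34.77607	26.43263	61.35096	248.551
GRMZM2G047368	ZmPIP2;6	28.2033	18.13528	53.17567	199.4343
GRMZM2G168439	ZmTIP1;2	124.288	11.90748	13.80556	12.93096
GRMZM2G027098	ZmTIP2;1	84.54834	136.8424	174.5521	380.7838
GRMZM2G056908	ZmTIP2;2	4.553362	5.91993	7.847642	21.60773
GRMZM2G125023	ZmTIP2;3	16.41429	1.501289	0.66028	0.912982
GRMZM2G305446	ZmTIP3;1	1.72853	0.06663	0*	0*
GRMZM2G103983	ZmTIP3;2	15.56036	0.91543	0.686821	1.139873
GRMZM2G108273	ZmTIP4;2	0.028412	0.11653	8.459535	13.80056
GRMZM2G093090	ZmTIP4;4	10.02319	0.695458	0.034258	0*
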