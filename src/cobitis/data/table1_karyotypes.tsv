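category	E	T	N	EE	TT	NN	ET	EN	EET	ETT	EEN	ENN
metacentric	11	5	5	22	10	10	16	16	27	21	27	21
submetacentric	13	9	13	26	18	26	22	26	35	31	39	39
subtelocentric	1	1	3	2	2	6	2	4	3	3	5	7
acrocentric	-	9	4	-	18	8	9	4	9	18	4	8
total	25	24	25	50	48	50	49	50	74	73	75	75
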