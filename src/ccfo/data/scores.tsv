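ccfo_id	level	rockwood	will_fix	relevance
11213	able	1	M	H
11213	with-difficulty	3.33	M	H
11213	unable	4	M	H
11214	able	2.67		TIED L+H
11214	with-difficulty	5.11		TIED L+H
11214	unable	7.44		TIED L+H
112121	able	3	M	H
112121	with-difficulty	6	M	H
1121221	only-level	8	L	H
1121222	paraplegic	6	L	TIED M+
1121222	quadriplegic	8	L	TIED M+
1121223	only-level	6	M	H
112442	able	3	L	H
112442	with-difficulty	4	L	H
112442	unable	7	L	H
112443	able	1	L	H
112443	with-difficulty	4	L	H
112443	unable	7	L	H
112412	able	2	H	H
112412	with-difficulty	3	H	H
112412	unable	5.5	H	H
131	only-level		H	H
1323	only-level		H	H
11231	only-level		H	H
113331	only-level			L
113332	only-level			L
113333	only-level			L
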