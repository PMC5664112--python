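pos	expected_allele
73	C
146	G
150	G
152	A
182	T
194	T
198	A
247	G
263	G
285	G
513	G
601	A
709	G
750	T
1007	T
1438	T
1700	C
2218	G
2706	G
2758	G
4769	T
5460	T
5999	G
6485	C
7028	T
7581	C
8860	C
9545	C
9667	T
10410	G
10664	A
11719	A
11914	C
12308	T
12372	T
12879	C
13104	G
13276	T
13422	T
14070	C
14212	G
14766	C
14902	A
15148	C
15326	C
15511	T
16189	C
16230	T
16249	C
16327	G
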