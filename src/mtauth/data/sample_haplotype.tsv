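notation	position	insertion_index	ref	alt	kind
73C	73	0		C	substitution
263G	263	0		G	substitution
285G	285	0		G	substitution
309.1C	309	1		C	insertion
309.2C	309	2		C	insertion
601A	601	0		A	substitution
750T	750	0		T	substitution
1438T	1438	0		T	substitution
1700C	1700	0		C	substitution
2218G	2218	0		G	substitution
2706G	2706	0		G	substitution
3107C	3107	0		C	substitution
3158.1T	3158	1		T	insertion
4769T	4769	0		T	substitution
5480G	5480	0		G	substitution
5999G	5999	0		G	substitution
7028T	7028	0		T	substitution
7581C	7581	0		C	substitution
8573A	8573	0		A	substitution
8860C	8860	0		C	substitution
9667T	9667	0		T	substitution
10410G	10410	0		G	substitution
11719A	11719	0		A	substitution
12308T	12308	0		T	substitution
12372T	12372	0		T	substitution
12879C	12879	0		C	substitution
13104G	13104	0		G	substitution
13422T	13422	0		T	substitution
14070C	14070	0		C	substitution
14766C	14766	0		C	substitution
14902A	14902	0		A	substitution
15148C	15148	0		C	substitution
15326C	15326	0		C	substitution
15511T	15511	0		T	substitution
16129A	16129	0		A	substitution
16189C	16189	0		C	substitution
16249C	16249	0		C	substitution
16327G	16327	0		G	substitution
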