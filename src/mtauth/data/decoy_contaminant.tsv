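notation	position	insertion_index	ref	alt	kind
2259T	2259	0		T	substitution
7337G	7337	0		G	substitution
15002C	15002	0		C	substitution
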