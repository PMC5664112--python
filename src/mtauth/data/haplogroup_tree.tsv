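node	parent	defining_variants
ROOT		
R	ROOT	73C,263G,750T,1438T,2706G,4769T,7028T,8860C,11719A,14766C,15326C,146G!,150G!,152A!,182T!
U	R	12308T,12372T,194T!,198A!,247G!
U1	U	285G,12879C,14070C,15148C,16249C,513G!,709G!,1007T!
U1a	U1	13104G,16189C,2758G!,5460T!
U1a1	U1a	2218G,6485C!,9545C!
U1a1a	U1a1	601A,1700C,5999G,7581C,9667T,10410G,13422T,14902A,15511T,16327G,10664A!,11914C!,13276T!,14212G!,16230T!,3158.1T
U1a1a1	U1a1a	11467A
U5	U	3197A,9477A,16270A
U2	U	1811T,16051G
K	U	1189C,10550G,14798G
U1b	U1	2100G,16327G
HV	R	11146A
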