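wildtype	line	total	sbs	indels
H492	H494	2455	2101	354
H492	H495	145	110	35
H492	H496	66813	59315	7498
H499	H512	21101	18860	2241
H574	H579	8503	7257	1246
H574	H580	6196	5528	668
H574	H592	23689	20548	3141
H574	H593	6633	5860	773
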