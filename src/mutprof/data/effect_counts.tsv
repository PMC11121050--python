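line	synonymous	nonsynonymous	nonsense	frameshift
H494	63	62	1	3
H495	0	2	1	0
H496	1411	1728	39	75
H512	328	465	10	22
H579	327	302	11	15
H580	105	130	3	7
H592	593	496	7	20
H593	123	116	3	7
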