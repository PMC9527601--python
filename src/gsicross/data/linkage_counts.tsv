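population	parent	locus_a	locus_b	recombinants	total
FW	RW	S	AP2	13	97
FW	RW	S	KSN	19	97
FW	TF	S	AP2	39	97
94/1	93/1-119	S	AP2	11	50
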