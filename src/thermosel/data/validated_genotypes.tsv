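snp_id	location	allele	genotypes
22585-1	Upstream	C>T	TT CT CC
24709	Intron	T>A	AA AT TT
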