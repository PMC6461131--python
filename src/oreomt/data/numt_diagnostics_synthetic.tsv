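position	mt_allele	numt_allele
16299	T	C
16307	G	A
16315	C	T
16323	T	C
16331	A	G
16339	A	G
16347	G	A
16355	C	T
16363	G	A
16385	A	G
16392	T	C
16399	C	T
16406	G	A
16412	C	T
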