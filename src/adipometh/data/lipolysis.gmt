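LIPOLYSIS_PRINTED	lipolysis-pathway genes with reported DMS + differential expression (18 of the 67-gene review list; supply the full list to reproduce set-level counts)	ABHD5	ADCY2	ADCY6	ADCY7	ADRB1	CIDEA	CIDEC	EDNRA	EDNRB	GNG7	IL6R	INSR	NPR1	PDE3B	PDE5A	PLIN2	PPARG	PRKAR2B
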