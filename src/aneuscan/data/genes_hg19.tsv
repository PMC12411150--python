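chrom	start	end	symbol	cytoband
chr7	55086714	55324313	EGFR	7p11.2
chr8	128748315	128753680	MYC	8q24.21
chr17	37844167	37886679	ERBB2	17q12
chr18	48556583	48611411	SMAD4	18q21.2
chr18	49866542	51062273	DCC	18q21.2
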