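# SNPs causing functionally significant structural rearrangements of
# transcripts (stop loss/gain, frameshift) in the focal strain. The fourth
# row's chromosome field is blank in the printed source; it is assigned
# chromosome 20 from its row grouping. Strain lists exclude the focal strain
# (every variant is carried by the focal strain by definition); names are
# normalised (ISIAH -> ISIAH/Icgn).
chrom	pos	gene	transcript_id	classification	hgvs_c	strains
7	120652704	Csnk1e	ENSRNOT00000018126	stop_lost	c.1521A>G	SBH/Ygl
7	120658002	Csnk1e	ENSRNOT00000087800	stop_gained	c.1083G>A	SBH/Ygl;ISIAH/Icgn
20	6556093	Lemd2	ENSRNOT00000035819	frameshift_variant	c.141dup	ISIAH/Icgn
20	46519455	AABR07045405.1	ENSRNOT00000077765	frameshift_variant	c.29del	ISIAH/Icgn
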