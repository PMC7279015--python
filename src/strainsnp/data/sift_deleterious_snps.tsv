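# Missense SNPs classified deleterious by SIFT (score <= 0.05) in the focal
# strain, one row per variant x transcript annotation; rows with an empty
# hgvs_c/aa_change repeat a variant on an additional transcript. Strain
# lists exclude the focal strain; names are normalised (ISIAH -> ISIAH/Icgn).
chrom	pos	snp_id	gene	transcript_id	hgvs_c	aa_change	strains
3	46597362	rs198261397	Pla2r1	ENSRNOT00000079261	c.355G>A	Glu119Lys	SBH/Ygl;SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin
3	46597362	rs198261397	Pla2r1	ENSRNOT00000011003	c.574G>A	Glu192Lys	SBH/Ygl;SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin
3	164232288		Spata2	ENSRNOT00000012604	c.632G>A	Arg211Gln	ISIAH/Icgn
5	145185401		Zmym6	ENSRNOT00000019135	c.2983C>T	Arg995Cys	ISIAH/Icgn
5	145185401		Zmym6	ENSRNOT00000079732	c.3100C>T	Arg1034Cys	ISIAH/Icgn
5	147824835		Ccdc28b	ENSRNOT00000075659	c.499C>T	Arg167Cys	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn
5	147824835		Ccdc28b	ENSRNOT00000083369			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn
7	77988396		Slc25a32	ENSRNOT00000006029	c.947G>T	Thr316Ile	ISIAH/Icgn
7	113986760		Trappc9	ENSRNOT00000038172	c.3397C>T	Arg1133Cys	MHS/Gib;ISIAH/Icgn
7	117497524		Mroh1	ENSRNOT00000081632	c.3022C>T	Arg1008Cys	ISIAH/Icgn
7	117723996		Kifc2	ENSRNOT00000085152	c.307G>A	Gly103Arg	ISIAH/Icgn
7	117723996		Kifc2	ENSRNOT00000093128			ISIAH/Icgn
13	99281863		Ephx1	ENSRNOT00000004780	c.296A>T	Asn99Ile	ISIAH/Icgn
13	99281863		Ephx1	ENSRNOT00000085279			ISIAH/Icgn
17	32136113		Nqo2	ENSRNOT00000024141	c.370G>A	Gly124Arg	ISIAH/Icgn
17	63123745		Gtpbp4	ENSRNOT00000074389	c.905A>G	Glu302Gly	ISIAH/Icgn
20	5414829		RT1-A1	ENSRNOT00000041590	c.124C>T	Arg42Trp	ISIAH/Icgn
20	5414829		RT1-A1	ENSRNOT00000078972	c.133C>T	Arg45Trp	ISIAH/Icgn
20	5414829		RT1-A1	ENSRNOT00000080900			ISIAH/Icgn
20	47395226		Ostm1	ENSRNOT00000057116	c.182T>C	Leu61Ser	ISIAH/Icgn
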