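# Most-common SNP table: focal-strain variants shared with >= 6 hypertensive
# strains/substrains (one row per variant x gene annotation; strain lists
# include the focal strain OXYS/Icgn). Strain names are normalised to the
# full strain/substrain form (e.g. ISIAH -> ISIAH/Icgn).
gene	chrom	pos	snp_id	classification	hgvs_c	aa_change	strains
Pla2r1	3	46597362	rs198261397	missense_variant	c.574G>A	Glu192Lys	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;SBH/Ygl;OXYS/Icgn
AC132627.2	5	147674509	rs197330026	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147674509	rs197330026	synonymous_variant	c.618A>C	Ala206Ala	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147685455	rs198904367	intron_variant	c.1148-981A>G		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;OXYS/Icgn
Bsdc1	5	147688443	rs198439815	3_prime_UTR_variant	c.*57A>C		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147688529	rs198616603	3_prime_UTR_variant	c.*143C>T		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147688798	rs197462955	3_prime_UTR_variant	c.*412C>T		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147688823	rs198095674	3_prime_UTR_variant	c.*437C>T		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Bsdc1	5	147688857	rs198680609	3_prime_UTR_variant	c.*471G>A		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Ccdc28b	5	147824835		missense_variant	c.499C>T	Arg167Cys	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Ccdc28b	5	147827114		intron_variant	c.164+134C>T		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;OXYS/Icgn
Fam229a	5	147688443	rs198439815	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Fam229a	5	147688529	rs198616603	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Fam229a	5	147688798	rs197462955	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Fam229a	5	147688823	rs198095674	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Fam229a	5	147688857	rs198680609	upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Iqcc	5	147824835		upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Iqcc	5	147827114		upstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;OXYS/Icgn
Kpna6	5	147852765		3_prime_UTR_variant	c.*478G>A		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Rbbp4	5	147508661	rs197189353	synonymous_variant	c.873G>A	Thr291Thr	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
RGD1561149	5	147407313	rs198649532	missense_variant	c.2327C>T	Ser776Leu	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tssk3	5	147685455	rs198904367	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;OXYS/Icgn
Tssk3	5	147688443	rs198439815	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tssk3	5	147688529	rs198616603	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tssk3	5	147688798	rs197462955	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tssk3	5	147688823	rs198095674	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tssk3	5	147688857	rs198680609	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Yars	5	147407313	rs198649532	downstream_gene_variant			SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Zbtb8os	5	147541343	rs106772412	synonymous_variant	c.144C>G	Thr48Thr	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;ISIAH/Icgn;OXYS/Icgn
Tmem132c	12	33016103	rs198544729	synonymous_variant	c.783G>C	Gly261Gly	SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;OXYS/Icgn
Fech	18	59942888	rs13449838	3_prime_UTR_variant	c.*702G>A		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;SBH/Ygl;ISIAH/Icgn;OXYS/Icgn
Fech	18	59943052	rs199183859	3_prime_UTR_variant	c.*538G>A		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;SBH/Ygl;ISIAH/Icgn;OXYS/Icgn
Fech	18	59943291	rs13449883	3_prime_UTR_variant	c.*299A>G		SHR/OlaIpcv;SHRSP/Gla;SHR/NCrlPrin;SHR/NHsd;SHR/OlaIpcvPrin;SBH/Ygl;ISIAH/Icgn;OXYS/Icgn
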