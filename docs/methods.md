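# Methods

## Filtering model

Per-animal transcriptome variant calls carry three pieces of evidence per
site: a phred-like site quality (VCF QUAL), per-animal genotype (GT) and
per-animal depth (DP). A site becomes a strain-level SNP for one
experimental group when

* site quality ≥ `min_q` (default 100),
* at least `min_hom` animals (default 3) of the group are homozygous for
  the **same** alternate allele — discordant homozygotes do not count, and
* at least one of those homozygous animals has DP ≥ `min_dp` (default 10).

The quality floor is applied at the site (variant) level: Q = 100 is the
conventional variant-quality floor of samtools-era pipelines, and a
per-read mapping-quality interpretation is not recoverable from VCF input.
Multiallelic records are decomposed per alternate allele before any rule is
applied, so every downstream comparison is allele-specific. Only
single-nucleotide variants and 1-bp insertions/deletions are supported. A
variant is kept if **any one** group accepts it; group lists are united by
(chrom, pos, alt), and the same site with different alternate alleles in
different groups stays as two variants.

## Panel comparison

The panel is a strains × loci matrix of homozygous alleles (inbred lines
carry one allele; heterozygous panel entries are treated as missing) with a
per-locus coverage mask restricting all comparisons to loci inside the
focal transcriptome. Carriage is exact allele match; missing genotypes
never count as carriage and stay in the denominator of nothing (the paper
trail for a missing-data rule does not exist, so the simplest non-carrier
interpretation is used). Partition labels are a pure function of carrier
categories, with control sharing dominating: a variant carried by both a
control and a hypertensive strain is control-shared. Sharing counts "out
of 13" include the focal strain itself, since a focal variant is by
definition carried by the focal strain.

## Consequence annotation

Annotation is per variant × transcript over transcripts whose span ± 5,000
bp contains the variant (5 kb is the customary up/downstream flank of
variant-effect annotation tools); a variant inside no flank is intergenic.
Coding SNVs are resolved by substituting the base into the reference codon
on the coding strand and translating with the standard nuclear code:
synonymous (residue unchanged), stop_gained (alternate codon is a stop
before the reference stop), stop_lost (reference stop destroyed), else
missense. One-bp coding indels always shift the frame. Splice-region
membership covers the last/first 3 exonic bases of intron-adjoining exon
ends and intronic bases 1–8 from the exon; the canonical donor/acceptor
dinucleotides are reported under the same `splice_region_variant` term
because the downstream tables use no finer splice classes. Transcripts
flagged with the nonsense-mediated-decay biotype append
`NMD_transcript_variant`. Impact is the most severe tier among a record's
terms (HIGH: frameshift/stop gained/stop lost; MODERATE: missense; LOW:
splice region/synonymous; MODIFIER: everything else).

CDS intervals *include* the stop codon, in the models and in the GTF the
package writes; a spliced CDS is therefore `ATG … stop` with length
divisible by three.

HGVS c. coordinates number coding bases 1..n from the A of ATG, 5' UTR
bases negatively, 3' UTR bases as `*k` past the stop codon, and intronic
bases against the nearest exon boundary (`c.164+134`, `c.1148-981`; ties
anchor to the upstream exon). One-bp deletions are `c.<pos>del`; a 1-bp
insertion that copies its coding 5' neighbour is `c.<pos>dup`, otherwise
`c.<a>_<b>insN`. Formatting uses no whitespace; the parser tolerates the
spaced typography seen in print. Protein names use 3-letter residues in
the compact `Glu192Lys` style (synonymous: `Ala206Ala`; stop: `Ter`).

SIFT scores are inputs, never computed (they require external homology
databases); the 0.05 boundary is classified deleterious, the conventional
reading of the ≤ 0.05 rule.

## Strain similarity

IBS between two strains is the fraction of matching alleles over loci
genotyped in both (pairwise-complete; per-pair denominators). With
homozygous dosages g ∈ {0, 2} this equals mean((2 − |g_i − g_j|)/2). The
dendrogram applies average linkage (UPGMA) to D = 1 − IBS — the linkage is
not dictated by the use case, but UPGMA matches the common usage of the
IBS-analysis tooling and yields ultrametric trees whose two-strain join
height is d/2. Classical MDS double-centres −½·J·D²·J, takes the top-k
eigenpairs, scales eigenvectors by √λ (negative eigenvalues clipped to
zero), and fixes each axis's sign by making its largest-magnitude loading
positive, so embeddings are fully deterministic.

## Synthetic data

The generator emulates the *structure* of the study's data, not its scale:

* **Genome/annotation.** 2 contigs × 90 kb, 8 genes on an 18-kb pitch
  (far enough apart that no variant is within 5 kb of two genes): coding
  genes on both strands (3 exons, UTRs, 900-bp CDS), transcripts flagged
  for nonsense-mediated decay (premature stop 200 bp before the last exon
  junction), and non-coding genes. Gene bodies are assembled from designed
  codons, so wobble sites, a TGG codon one substitution from a stop, exon
  boundary codons and the stop codon itself sit at known coordinates —
  planting a variant of any published effect class is table lookup, not
  search.
* **Panel.** The 45 panel strains of the study (12 hypertensive incl. a
  sister strain derived from the same founder stock as the focal strain,
  11 normotensive, 22 other controls). Sharing blocks plant 201 pass-fated
  focal SNPs: a dominant sister-only block, hypertensive blocks of up to 8
  carriers (focal included; never all 13), control-shared blocks (the
  largest, mirroring the real funnel where control-shared variants
  dominate, and including the sister strain as ancestral variation), and
  focal-exclusive variants. 300 background panel-only loci add clade
  structure (an SHR-like substrain block, private alleles per strain, a
  handful of sister-private alleles) so the similarity stage has realistic
  contrast. Non-carrier genotypes go missing at rate 0.03.
* **Calls.** 3 groups × 4 animals. Depth is negative-binomial
  (mean 30, dispersion 4 — heavier-tailed than Poisson, producing natural
  DP boundary cases); site quality is 100 + Exponential(700) for passing
  sites. Each fail fate violates exactly one criterion in every group
  (only 2 homozygotes / DP ≤ 9 everywhere / QUAL < 100), pass fates
  satisfy all three in every group, and heterozygous noise is added both
  at planted sites (beyond the three guaranteed homozygotes, rate 0.02)
  and at 40 noise-only sites. The truth table therefore *implies* the
  filter output exactly, which is what the recovery tests assert.
* **Coverage.** Planted (transcriptome-derived) loci are always covered;
  background loci are covered with probability `coverage_fraction`
  (default 0.8). The degenerate request `coverage_fraction = 0` marks
  nothing covered, modelling "no comparable loci".

Everything is driven by `numpy.random.default_rng([seed, stage])`; a
scenario plus seed reproduces every output file byte for byte.

What the generator does **not** emulate: read-level artifacts (alignment
error, allelic imbalance, strand bias), linkage disequilibrium beyond the
planted blocks, transcript isoform diversity (one transcript per gene),
genotype-likelihood uncertainty, and genome-scale locus counts. Passing
tests show the pipeline's logic is exact on data matching its assumptions;
they do not validate caller/aligner behaviour on real reads.

## Worked-example tables

The published most-common/high-impact/deleterious SNP tables are shipped as
TSV fixtures (strain names normalised to full substrain form; one printed
row with a blank chromosome field is assigned chromosome 20 from its row
grouping, noted in the fixture header). Phenotype-association flags
(hypertension / neurodegenerative / mental disorders) are an opaque input
table, replacing live disease-database queries that cannot be reproduced
as of a fixed date.

## Candidate ranking

Deterministic lexicographic order: protein-structure/function-changing
first (HIGH impact or SIFT-deleterious), then number of hypertensive
carriers descending, then phenotype-flag count descending, then
(chrom, pos, alt). This reproduces the verbal prioritisation that nominated
*Pla2r1* and *Ccdc28b* (deleterious missense, shared with six other
hypertensive strains) ahead of the non-coding and narrowly shared variants.

## Numerical and engineering choices

* Counting units are explicit everywhere the published tables are
  ambiguous: effect-class summaries report both annotation rows
  (variant × transcript) and distinct variants.
* MDS eigenvalues are clipped at zero for coordinate scaling but reported
  unclipped; `k` must be ≤ n − 1.
* IBS raises on a strain pair with zero co-genotyped loci rather than
  imputing; UPGMA requires a symmetric zero-diagonal matrix.
* Problem sizes in tests (2 × 90 kb genome, 210 planted variants, 46
  strains, 500-variant annotation oracle sweeps) were chosen so the whole
  suite exercises every code path in a few seconds while keeping every
  planted margin (e.g. sister-strain nearest-neighbour separation) far
  from tie-breaking noise.

## Known limitations

* Only SNVs and 1-bp indels; no MNVs, no multi-bp indels, no HGVS
  right-shifting beyond the single-base dup rule.
* HGVS p. names cover substitutions only (frameshift records carry a c.
  name but no protein name), matching the tables the output mirrors.
* The filter treats QUAL as group-level evidence; per-read mapping
  qualities are out of reach of VCF input by design.
* `non_coding_transcript_exon_variant` plus `splice_region_variant`
  combinations can occur on non-coding transcripts but are not planted by
  the default scenario.
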