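# strainsnp

Comparative strain genotyping for inbred rodent panels: reduce
transcriptome-derived per-animal variant calls to a strain-level SNP list,
compare it against a multi-strain genotype panel, classify transcript
consequences, and quantify inter-strain genetic similarity.

The package was built around a concrete use case: finding SNPs shared
between a senescence-accelerated, moderately hypertensive rat strain
(OXYS) and a panel of 45 rat strains and substrains — 12 hypertensive
models, 11 normotensive controls and 22 other controls — in order to
nominate candidate genes for the joint manifestation of hypertension and
accelerated aging. All of the machinery is generic, though: any focal
strain, panel, and category labelling works.

## What it computes

1. **Variant filtering.** A site called in per-animal RNA-seq data is
   accepted as a strain-level SNP when site quality Q ≥ 100, at least three
   animals of one experimental group are homozygous for the same alternate
   allele, and read depth DP ≥ 10 in at least one of those animals.
   Group-level lists are united across tissue/age groups.
2. **Panel comparison.** Each SNP is profiled against the panel at loci
   covered by the focal transcriptome and partitioned: *control-shared*
   (carried by any normotensive/other control — control sharing dominates),
   *hypertensive-shared*, or *focal-exclusive*. Exact-subset (UpSet-style)
   counts over the hypertensive strains and a "most common" selection
   (shared by ≥ 6 of the 13 hypertensive strains, focal included) follow.
3. **Consequence annotation.** Sequence Ontology terms per
   variant × transcript (missense/stop gained/stop lost/frameshift/
   synonymous/splice region/UTR/intronic/up- and downstream/intergenic,
   with NMD-transcript flags), impact tiers (HIGH/MODERATE/LOW/MODIFIER),
   HGVS c. and p. names (`c.574G>A`, `Glu192Lys`), and thresholding of
   externally supplied SIFT scores (≤ 0.05 → deleterious).
4. **Strain similarity.** Identity-by-state matrix
   IBS(i,j) = mean over co-genotyped loci of (2 − |g_i − g_j|)/2,
   a UPGMA dendrogram of D = 1 − IBS (newick output), and classical
   multidimensional scaling (principal coordinates) of the same distances.
5. **Reporting.** Effect-class summaries, locus-cluster counts, and a
   deterministic candidate ranking (protein-changing first, then breadth of
   hypertensive sharing, then phenotype-association flags).

A synthetic-data generator (`strainsnp.simulate`) produces a small genome,
gene models on both strands (including an NMD-flagged and a non-coding
transcript), a 45-strain panel with block-structured allele sharing, and
per-animal call sets — together with a truth table of every planted
variant's strain subset, intended consequence and intended filter fate, so
the whole pipeline is testable end to end without any external data.

## Worked example

```python
from strainsnp import reporting as rep

t1 = rep.load_most_common_table()      # SNPs shared with >= 6 hypertensive strains
t3 = rep.load_high_impact_table()      # transcript-rearranging SNPs
t4 = rep.load_deleterious_table()      # SIFT-deleterious missense SNPs

print("rows:", len(t1), "genes:", rep.count_distinct_genes(t1))
print("max sharing:", rep.max_sharing_count(t1))
print("chr5 147.4-147.9 Mb cluster:", rep.count_locus_cluster(t1, "5", 147_400_000, 147_900_000))
print("deleterious variants:", rep.count_distinct_variants(t4))
print("high-impact variants:", rep.count_distinct_variants(t3))
cands = rep.candidates_from_tables(t1, t4, rep.load_gene_phenotypes())
print("top candidates:", [c.gene for c in cands[:2]])
```

prints

```
rows: 33 genes: 14
max sharing: 8
chr5 147.4-147.9 Mb cluster: 11
deleterious variants: 13
high-impact variants: 4
top candidates: ['Pla2r1', 'Ccdc28b']
```

i.e. the 33 most-shared variant×gene annotations fall in 14 genes, no SNP
is shared by more than 8 of the 13 hypertensive strains, 11 of the 14 genes
cluster in a 0.5-Mb window of chromosome 5, 13 SNPs are SIFT-deleterious,
4 rearrange transcript structure, and the two genes that are both
deleterious-missense and widely shared (*Pla2r1*, *Ccdc28b*) rank first.

The full synthetic pipeline runs from the shell:

```bash
strainsnp run-all --input-dir inputs --output-dir outputs --seed 1
```

which simulates the fixtures, filters the per-animal calls, profiles them
against the panel, annotates consequences, computes IBS/UPGMA/MDS, and
writes a manifest with the per-stage variant funnel.

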