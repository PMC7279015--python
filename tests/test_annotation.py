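"""Consequence calling: codon worked example, rebuild-and-diff oracle,
strand symmetry, splice-region windows, impact tiers, SIFT thresholds."""

import numpy as np
import pytest

from oracles import rebuild_and_diff
from strainsnp.annotation import (
    IMPACT_HIGH,
    IMPACT_MODERATE,
    annotate,
    classify_sift,
    impact_of,
)
from strainsnp.hgvs import hgvs_c, parse_hgvs_c
from strainsnp.transcripts import TranscriptModel, reverse_complement
from strainsnp.variants import Variant


@pytest.fixture(scope="module")
def glu192_setup():
    """Single-exon transcript whose CDS base 574 is the G of codon 192 (GAA)."""
    n_codons = 200
    codons = ["ATG"] + ["GCT"] * (n_codons - 2) + ["TAA"]
    codons[191] = "GAA"  # codon 192
    cds = "".join(codons)
    utr5, utr3 = "TTTTTTTTTT", "CCCCCCCCCCCCCCCCCCCC"
    seq = utr5 + cds + utr3
    genome = {"chr1": seq}
    tx = TranscriptModel(
        gene_id="g1", gene_symbol="Pla2r1_like", transcript_id="t1",
        chrom="chr1", strand="+", exons=((1, len(seq)),),
        cds_start=len(utr5) + 1, cds_end=len(utr5) + len(cds),
    )
    return genome, tx


def test_codon_192_glu_to_lys_missense(glu192_setup):
    genome, tx = glu192_setup
    variant = Variant("chr1", 10 + 574, "G", "A")
    (rec,) = annotate(variant, [tx], genome)
    assert rec.so_terms == ("missense_variant",)
    assert rec.hgvs_c == "c.574G>A"
    assert rec.hgvs_p == "Glu192Lys"


def test_synonymous_protein_name_repeats_the_residue(glu192_setup):
    genome, tx = glu192_setup
    # third base of an alanine GCT codon: GCT -> GCC
    variant = Variant("chr1", 10 + 6, "T", "C")
    (rec,) = annotate(variant, [tx], genome)
    assert rec.so_terms == ("synonymous_variant",)
    assert rec.hgvs_p == "Ala2Ala"


def test_variant_beyond_flank_is_intergenic(glu192_setup):
    genome, tx = glu192_setup
    genome = {"chr1": genome["chr1"] + "A" * 20000}
    variant = Variant("chr1", tx.end + 10001, "A", "G")
    (rec,) = annotate(variant, [tx], genome)
    assert rec.so_terms == ("intergenic_variant",)
    assert rec.transcript_id is None
    # just inside the flank: downstream for a plus-strand transcript
    (rec2,) = annotate(Variant("chr1", tx.end + 5000, "A", "G"), [tx], genome)
    assert rec2.so_terms == ("downstream_gene_variant",)


def test_reference_mismatch_raises(glu192_setup):
    genome, tx = glu192_setup
    with pytest.raises(ValueError, match="reference mismatch"):
        annotate(Variant("chr1", 1, "G", "A"), [tx], genome)


def test_random_snvs_match_full_rebuild_oracle(reference):
    """500 random SNVs: per-transcript SO terms equal those of an oracle
    that rebuilds the whole mRNA/protein before and after the edit."""
    rng = np.random.default_rng(11)
    genome = reference.contigs
    contigs = list(genome)
    checked = 0
    for _ in range(500):
        chrom = contigs[rng.integers(0, len(contigs))]
        pos = int(rng.integers(1, len(genome[chrom]) + 1))
        ref = genome[chrom][pos - 1]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        variant = Variant(chrom, pos, ref, alt)
        records = {
            r.transcript_id: set(r.so_terms)
            for r in annotate(variant, reference.transcripts, genome)
        }
        oracle = {
            tx.transcript_id: terms
            for tx in reference.transcripts
            if (terms := rebuild_and_diff(variant, tx, genome)) is not None
        }
        if not oracle:
            assert records == {None: {"intergenic_variant"}}
        else:
            assert records == oracle, str(variant)
        checked += 1
    assert checked == 500


def test_planted_consequences_match_annotation(reference, truth):
    """Every planted variant annotates to its intended term combination on
    its target transcript; all published effect-class strings are realised."""
    genome = reference.contigs
    seen = set()
    for row in truth.frame.itertuples():
        variant = Variant(row.chrom, int(row.pos), row.ref, row.alt)
        records = annotate(variant, reference.transcripts, genome)
        if row.transcript_id:
            (rec,) = [r for r in records if r.transcript_id == row.transcript_id]
        else:
            (rec,) = records
        assert rec.consequence == row.consequence
        seen.add(rec.consequence)
    from strainsnp.simulate import TABLE2_COMBINATIONS

    assert set(TABLE2_COMBINATIONS) <= seen


def _mirror(genome, tx, variant):
    """Reverse-complement the world; names must be unchanged."""
    length = {c: len(s) for c, s in genome.items()}
    mirrored_genome = {c: reverse_complement(s) for c, s in genome.items()}

    def mpos(c, p):
        return length[c] - p + 1

    exons = tuple(
        sorted((mpos(tx.chrom, e), mpos(tx.chrom, s)) for s, e in tx.exons)
    )
    cds = (
        tuple(sorted((mpos(tx.chrom, tx.cds_end), mpos(tx.chrom, tx.cds_start))))
        if tx.is_coding
        else (None, None)
    )
    mirrored_tx = TranscriptModel(
        gene_id=tx.gene_id, gene_symbol=tx.gene_symbol,
        transcript_id=tx.transcript_id, chrom=tx.chrom,
        strand="-" if tx.strand == "+" else "+",
        exons=exons, cds_start=cds[0], cds_end=cds[1], biotype=tx.biotype,
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mirrored_variant = Variant(
        variant.chrom, mpos(variant.chrom, variant.pos),
        comp[variant.ref], comp[variant.alt],
    )
    return mirrored_genome, mirrored_tx, mirrored_variant


def test_strand_symmetry_of_names_and_terms(reference, truth):
    genome = reference.contigs
    tx_by_id = {t.transcript_id: t for t in reference.transcripts}
    rows = truth.frame[
        (truth.frame.transcript_id != "")
        & (truth.frame.ref.str.len() == 1)
        & (truth.frame.alt.str.len() == 1)
    ].head(40)
    for row in rows.itertuples():
        tx = tx_by_id[row.transcript_id]
        variant = Variant(row.chrom, int(row.pos), row.ref, row.alt)
        (rec,) = [
            r
            for r in annotate(variant, [tx], genome)
            if r.transcript_id == tx.transcript_id
        ]
        mg, mtx, mv = _mirror(genome, tx, variant)
        (mrec,) = [
            r
            for r in annotate(mv, [mtx], mg)
            if r.transcript_id == tx.transcript_id
        ]
        assert mrec.so_terms == rec.so_terms
        assert mrec.hgvs_c == rec.hgvs_c
        assert mrec.hgvs_p == rec.hgvs_p


def test_splice_region_windows():
    # 2-exon plus-strand coding transcript with a 100-bp intron
    utr5 = "T" * 10
    cds = "ATG" + "GCT" * 31 + "TAA"  # 99 bases
    exon1_seq = utr5 + cds[:45]
    intron = "G" * 100
    exon2_seq = cds[45:] + "C" * 10
    seq = exon1_seq + intron + exon2_seq
    genome = {"chr1": seq}
    e1 = (1, len(exon1_seq))
    e2 = (len(exon1_seq) + 101, len(seq))
    tx = TranscriptModel(
        "g", "G", "t", "chr1", "+", (e1, e2),
        cds_start=11, cds_end=e2[0] + len(cds) - 46,
    )
    def terms_at(pos):
        (rec,) = annotate(Variant("chr1", pos, seq[pos - 1],
                                  "ACGT".replace(seq[pos - 1], "")[0]),
                          [tx], genome)
        return rec.so_terms

    assert "splice_region_variant" in terms_at(e1[1])       # last exon base
    assert "splice_region_variant" in terms_at(e1[1] - 2)   # 3rd-last base
    assert "splice_region_variant" not in terms_at(e1[1] - 3)
    assert "splice_region_variant" in terms_at(e1[1] + 1)   # donor
    assert "splice_region_variant" in terms_at(e1[1] + 8)
    assert "splice_region_variant" not in terms_at(e1[1] + 9)
    assert "splice_region_variant" in terms_at(e2[0] - 8)   # acceptor side
    assert "splice_region_variant" not in terms_at(e2[0] - 9)


def test_impact_tier_is_the_most_severe_term():
    assert impact_of(["stop_lost"]) == IMPACT_HIGH
    assert impact_of(["missense_variant", "NMD_transcript_variant"]) == IMPACT_MODERATE
    assert impact_of(["splice_region_variant", "3_prime_UTR_variant",
                      "NMD_transcript_variant"]) == "LOW"
    assert impact_of(["intron_variant"]) == "MODIFIER"
    with pytest.raises(ValueError):
        impact_of([])
    with pytest.raises(ValueError):
        impact_of(["made_up_variant"])


@pytest.mark.parametrize(
    "score,expected",
    [(0.01, "deleterious"), (0.50, "tolerated"), (0.05, "deleterious"),
     (0.0, "deleterious"), (1.0, "tolerated")],
)
def test_sift_threshold(score, expected):
    assert classify_sift(score) == expected


@pytest.mark.parametrize("score", [-0.1, 1.01])
def test_sift_rejects_out_of_range_scores(score):
    with pytest.raises(ValueError):
        classify_sift(score)
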