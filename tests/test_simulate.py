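"""Synthetic-data generator: determinism, layout validity, truth consistency."""

import dataclasses

import pytest
from Bio.Seq import Seq

from strainsnp.comparison import CATEGORY_FOCAL, CATEGORY_HYPERTENSIVE
from strainsnp.io import read_fasta
from strainsnp.simulate import (
    FATE_PASS,
    SISTER_STRAIN,
    SharingBlock,
    SimulationScenario,
    TABLE2_COMBINATIONS,
    default_scenario,
    generate_reference,
    generate_sample_calls,
    generate_strain_panel,
    simulate_to_dir,
)
from strainsnp.transcripts import read_gtf


def minimal_scenario(**overrides):
    base = dict(
        seed=5,
        n_contigs=1,
        contig_length=10_000,
        n_genes=1,
        strain_spec=(
            ("FOCAL", CATEGORY_FOCAL),
            ("HYP1", CATEGORY_HYPERTENSIVE),
        ),
        sharing_blocks=(SharingBlock(2, ("FOCAL", "HYP1")),),
        n_background_loci=10,
        n_noise_sites=5,
    )
    base.update(overrides)
    return SimulationScenario(**base)


def test_minimal_scenario_places_one_valid_gene():
    ref = generate_reference(minimal_scenario())
    assert len(ref.contigs) == 1
    assert len(ref.transcripts) == 1
    tx = ref.transcripts[0]
    assert len(tx.exons) >= 2
    cds = tx.spliced_cds(ref.contigs)
    assert cds.startswith("ATG")
    assert len(cds) % 3 == 0
    protein = str(Seq(cds).translate())
    assert protein.startswith("M") and protein.endswith("*")
    assert "*" not in protein[:-1]


def test_placement_failure_is_an_explicit_error():
    with pytest.raises(ValueError, match="cannot place"):
        generate_reference(minimal_scenario(contig_length=8_000))


def test_reference_rerun_is_byte_identical(tmp_path):
    sc = default_scenario(seed=7)
    a = simulate_to_dir(sc, tmp_path / "a")
    b = simulate_to_dir(sc, tmp_path / "b")
    for key in a.paths:
        assert a.paths[key].read_bytes() == b.paths[key].read_bytes(), key


def test_minus_strand_cds_translates_from_reverse_complement(reference):
    """A minus-strand gene's CDS, read off the genome by an independent
    reader (FASTA/GTF round-trip plus Biopython translation), is a valid ORF."""
    minus = [
        t for t in reference.transcripts if t.strand == "-" and t.is_coding
    ]
    assert minus
    for tx in minus:
        contig = reference.contigs[tx.chrom]
        lo, hi = sorted((tx.cds_start, tx.cds_end))
        parts = [
            contig[max(s, lo) - 1 : min(e, hi)]
            for s, e in tx.exons
            if min(e, hi) >= max(s, lo)
        ]
        cds = str(Seq("".join(parts)).reverse_complement())
        protein = str(Seq(cds).translate())
        assert protein.startswith("M") and protein.endswith("*")


def test_fixture_files_round_trip(tmp_path, scenario):
    out = simulate_to_dir(scenario, tmp_path / "sim")
    genome = read_fasta(out.paths["genome"])
    assert genome == out.reference.contigs
    transcripts = read_gtf(out.paths["gtf"])
    assert len(transcripts) == len(out.reference.transcripts)
    by_id = {t.transcript_id: t for t in out.reference.transcripts}
    for tx in transcripts:
        orig = by_id[tx.transcript_id]
        assert tx.exons == orig.exons
        assert (tx.cds_start, tx.cds_end) == (orig.cds_start, orig.cds_end)
        assert tx.biotype == orig.biotype


def test_every_planted_strain_subset_is_recorded(scenario, truth):
    by_block = truth.frame.groupby("block")
    for block in scenario.sharing_blocks:
        rows = by_block.get_group(block.label)
        assert len(rows) == block.n_variants
        assert set(rows.strains) == {";".join(block.strains)}


def test_sharing_block_with_unknown_strain_is_rejected():
    with pytest.raises(ValueError, match="unknown strains"):
        minimal_scenario(
            sharing_blocks=(SharingBlock(1, ("FOCAL", "NO_SUCH")),)
        )


def test_zero_coverage_fraction_leaves_no_comparable_loci():
    sc = minimal_scenario(coverage_fraction=0.0)
    ref = generate_reference(sc)
    panel, _ = generate_strain_panel(ref, sc)
    assert panel.restrict_to_covered().n_loci == 0


def test_all_consequence_classes_are_planted(truth):
    planted = set(truth.frame.consequence)
    assert set(TABLE2_COMBINATIONS) <= planted


def test_panel_strains_are_fully_homozygous(panel):
    # single allele string per strain per locus is homozygosity by
    # construction; check alleles are single defined values, never "het"
    import pandas as pd

    values = panel.genotypes.to_numpy(object).ravel()
    for v in values:
        assert v is None or isinstance(v, str)


def test_realized_calls_never_contradict_truth_fates(scenario, truth, calls):
    """Each fail fate violates exactly its criterion in every group; pass
    variants satisfy all three rules in every group."""
    for group in scenario.groups:
        by_site = {}
        for c in calls[group]:
            by_site.setdefault((c.chrom, c.pos, c.alt), []).append(c)
        for row in truth.frame.itertuples():
            site = by_site[(row.chrom, int(row.pos), row.alt)]
            hom = [c for c in site if c.gt == "hom_alt"]
            qual = max(c.site_q for c in site)
            if row.fate == FATE_PASS:
                assert len(hom) >= 3
                assert any(c.dp >= 10 for c in hom)
                assert qual >= 100
            elif row.fate == "fail:dp":
                assert all(c.dp <= 9 for c in site)
                assert len(hom) >= 3 and qual >= 100
            elif row.fate == "fail:min_hom":
                assert len(hom) <= 2
                assert qual >= 100
            else:  # fail:qual
                assert qual < 100
                assert len(hom) >= 3 and any(c.dp >= 10 for c in hom)


def test_sister_strain_blocks_dominate_sister_sharing(truth):
    sister_rows = truth.frame[
        truth.frame.strains.str.contains(SISTER_STRAIN, regex=False)
    ]
    assert len(sister_rows) > 0
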