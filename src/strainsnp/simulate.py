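"""Synthetic genome / panel / call-set generator with a planted truth table.

Everything downstream of raw sequencing is emulated at desk scale: a small
random genome carrying designed gene models (coding genes on both strands, a
transcript targeted by nonsense-mediated decay, a non-coding gene), a
45-strain genotype panel with block-structured allele sharing (a
near-identical sister strain, a clade of related substrains, distant
strains), per-animal transcriptome calls for a focal strain in several
tissue groups, and a truth table recording each planted variant's strain
subset, intended transcript consequence, and intended filter fate. The
scenario seed fully determines every output file byte-for-byte.

Gene bodies are assembled from designed codons, so every consequence-class
site (wobble positions, a tryptophan codon one substitution away from a stop,
exon-boundary codons, the stop codon itself) exists at a known coordinate in
every coding gene; planting never has to search.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .comparison import (
    CATEGORY_FOCAL,
    CATEGORY_HYPERTENSIVE,
    CATEGORY_NORMOTENSIVE,
    CATEGORY_OTHER,
    LABEL_CONTROL,
    LABEL_EXCLUSIVE,
    LABEL_HYPERTENSIVE,
    StrainPanel,
)
from .filtering import GT_HET, GT_HOM_ALT, GT_HOM_REF, GenotypeCall
from .io import build_vcf_header, write_bed_mask, write_fasta
from .transcripts import NMD_BIOTYPE, TranscriptModel, reverse_complement, write_gtf
from .variants import Variant

# ---------------------------------------------------------------------------
# strain panel of the emulated study: 12 hypertensive, 11 normotensive-control
# and 22 other-control strains, plus the focal strain
# ---------------------------------------------------------------------------

FOCAL_STRAIN = "OXYS/Icgn"
SISTER_STRAIN = "ISIAH/Icgn"
SHR_CLADE = (
    "SHR/OlaIpcv",
    "SHRSP/Gla",
    "SHR/NCrlPrin",
    "SHR/NHsd",
    "SHR/OlaIpcvPrin",
)
HYPERTENSIVE_STRAINS = (
    "FHH/EurMcwi",
    "LH/MavRrrc",
    "MHS/Gib",
    "SBH/Ygl",
    *SHR_CLADE,
    "SS/Jr",
    "SS/JrHsdMcwi",
    SISTER_STRAIN,
)
NORMOTENSIVE_STRAINS = (
    "FHL/EurMcwi",
    "LN/MavRrrc",
    "LL/MavRrrc",
    "MNS/Gib",
    "SBN/Ygl",
    "SR/Jr",
    "WKY/N",
    "WKY/Gla",
    "WKY/NCrl",
    "WKY/NHsd",
    "WAG/GSto-Icgn",
)
OTHER_CONTROL_STRAINS = (
    "ACI/N",
    "ACI/EurMcwi",
    "BBDP/Wor",
    "BN-Lx/Cub",
    "BN-Lx/CubPrin",
    "BN/SsN",
    "BUF/N",
    "DA/BklArbNsi",
    "F334/N",
    "F344/NHsd",
    "F344/NCrl",
    "SUO_F344",
    "GK/Ox",
    "LE/Stm-SOLiD",
    "LEW/Crl",
    "LEW/NCrlBR",
    "LE/Stm-Illumina",
    "M520/N",
    "MR/N",
    "WAG/Rij",
    "WN/N",
    "Wistar/Icgn",
)

#: the realised consequence vocabulary: every term combination planted by the
#: default scenario, most severe first
TABLE2_COMBINATIONS: tuple[str, ...] = (
    "frameshift_variant",
    "stop_gained",
    "stop_lost",
    "missense_variant",
    "missense_variant, NMD_transcript_variant",
    "missense_variant, splice_region_variant",
    "splice_region_variant, synonymous_variant",
    "splice_region_variant, 3_prime_UTR_variant, NMD_transcript_variant",
    "synonymous_variant",
    "synonymous_variant, NMD_transcript_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "3_prime_UTR_variant, NMD_transcript_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "intron_variant, non_coding_transcript_variant",
    "intron_variant, NMD_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

_FILLER_CYCLE: tuple[str, ...] = (
    "intron_variant",
    "3_prime_UTR_variant",
    "downstream_gene_variant",
    "upstream_gene_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "intron_variant, non_coding_transcript_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant, NMD_transcript_variant",
    "intergenic_variant",
    "3_prime_UTR_variant, NMD_transcript_variant",
)

FATE_PASS = "pass"
FATE_FAIL_DP = "fail:dp"
FATE_FAIL_HOM = "fail:min_hom"
FATE_FAIL_QUAL = "fail:qual"
_FATES = (FATE_PASS, FATE_FAIL_DP, FATE_FAIL_HOM, FATE_FAIL_QUAL)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(list("ACGT"))

# codons free of stops, used as random CDS filler
_SAFE_CODONS = (
    "GCT GCC ACT ACC GGT GGC CCT TCT GTT GTC ATT ATC CAG GAG AAG TTC TAC CAT "
    "CGT AGC"
).split()


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadModel:
    """Per-sample sequencing model for the focal strain's call sets."""

    mean_depth: float = 30.0
    depth_dispersion: float = 4.0  # negative-binomial size parameter
    het_noise_rate: float = 0.02  # chance of a spurious het call per animal
    qual_scale: float = 700.0  # exponential scale of site QUAL above the floor


@dataclass(frozen=True)
class SharingBlock:
    """A set of planted variants shared by one exact strain subset."""

    n_variants: int
    strains: tuple[str, ...]  # must include the focal strain
    fate: str = FATE_PASS
    label: str = ""


@dataclass(frozen=True)
class SimulationScenario:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 90_000
    n_genes: int = 8
    strain_spec: tuple[tuple[str, str], ...] = ()
    sharing_blocks: tuple[SharingBlock, ...] = ()
    read_model: ReadModel = field(default_factory=ReadModel)
    coverage_fraction: float = 0.8
    groups: tuple[str, ...] = ("cortex", "hippocampus", "retina")
    n_animals_per_group: int = 4
    n_background_loci: int = 300
    n_noise_sites: int = 40

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.n_genes < 1 or self.contig_length < 1:
            raise ValueError("n_contigs, n_genes and contig_length must be >= 1")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")
        if self.n_animals_per_group < 3:
            raise ValueError("need >= 3 animals per group to realise pass fates")
        names = [name for name, _ in self.strain_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strain names in strain_spec")
        categories = dict(self.strain_spec)
        bad = set(categories.values()) - {
            CATEGORY_FOCAL,
            CATEGORY_HYPERTENSIVE,
            CATEGORY_NORMOTENSIVE,
            CATEGORY_OTHER,
        }
        if bad:
            raise ValueError(f"unknown strain categories: {sorted(bad)}")
        focal = [n for n, c in self.strain_spec if c == CATEGORY_FOCAL]
        if len(focal) != 1:
            raise ValueError("strain_spec must declare exactly one focal strain")
        for block in self.sharing_blocks:
            unknown = set(block.strains) - set(names)
            if unknown:
                raise ValueError(f"sharing block names unknown strains: {sorted(unknown)}")
            if focal[0] not in block.strains:
                raise ValueError("every sharing block must include the focal strain")
            if block.fate not in _FATES:
                raise ValueError(f"unknown filter fate {block.fate!r}")
            if block.n_variants < 0:
                raise ValueError("block variant counts must be >= 0")

    @property
    def focal_strain(self) -> str:
        return next(n for n, c in self.strain_spec if c == CATEGORY_FOCAL)

    @property
    def categories(self) -> dict[str, str]:
        return dict(self.strain_spec)

    @property
    def panel_strains(self) -> list[str]:
        return [n for n, c in self.strain_spec if c != CATEGORY_FOCAL]


def default_scenario(seed: int = 0) -> SimulationScenario:
    """The study-shaped default: 45-strain panel, sister strain nearly
    identical to the focal strain, an SHR-like substrain clade, sharing
    blocks reproducing the funnel (control-shared dominating, a maximum of 8
    hypertensive carriers including the focal strain, none shared by all 13),
    and planted pass/fail filter fates."""
    spec = (
        (FOCAL_STRAIN, CATEGORY_FOCAL),
        *((s, CATEGORY_HYPERTENSIVE) for s in HYPERTENSIVE_STRAINS),
        *((s, CATEGORY_NORMOTENSIVE) for s in NORMOTENSIVE_STRAINS),
        *((s, CATEGORY_OTHER) for s in OTHER_CONTROL_STRAINS),
    )
    blocks = (
        SharingBlock(60, (FOCAL_STRAIN, SISTER_STRAIN), label="sister_only"),
        SharingBlock(8, (FOCAL_STRAIN, SISTER_STRAIN, "SBH/Ygl"), label="sister_sbh"),
        SharingBlock(6, (FOCAL_STRAIN, *SHR_CLADE, SISTER_STRAIN), label="shr_clade_7"),
        SharingBlock(
            3, (FOCAL_STRAIN, *SHR_CLADE, "SBH/Ygl", SISTER_STRAIN), label="shr_clade_8"
        ),
        SharingBlock(5, (FOCAL_STRAIN, "MHS/Gib"), label="mhs"),
        SharingBlock(
            4, (FOCAL_STRAIN, "SS/Jr", "SS/JrHsdMcwi", "SBH/Ygl"), label="salt"
        ),
        SharingBlock(20, (FOCAL_STRAIN,), label="exclusive"),
        # ancestral Wistar-derived variation: shared by the sister strain and
        # by normotensive/other controls, so excluded as hypertension-specific
        SharingBlock(
            80,
            (FOCAL_STRAIN, SISTER_STRAIN, "WKY/N", "WKY/Gla", "ACI/N"),
            label="control",
        ),
        SharingBlock(
            15, (FOCAL_STRAIN, SISTER_STRAIN, "WAG/Rij"), label="control_sister"
        ),
        SharingBlock(3, (FOCAL_STRAIN,), fate=FATE_FAIL_DP, label="fail_dp"),
        SharingBlock(3, (FOCAL_STRAIN,), fate=FATE_FAIL_HOM, label="fail_hom"),
        SharingBlock(3, (FOCAL_STRAIN,), fate=FATE_FAIL_QUAL, label="fail_qual"),
    )
    return SimulationScenario(seed=seed, strain_spec=spec, sharing_blocks=blocks)


# ---------------------------------------------------------------------------
# gene layout plans
# ---------------------------------------------------------------------------

_GENE_PITCH = 18_000
_FIRST_GENE_OFFSET = 6_000
_FLANK = 5_000

# coding gene: 200 UTR5 | 150+300+450 CDS split by 1500/400-bp introns | 600 UTR3
_CODING_EXONS = ((1, 350), (1851, 2150), (2551, 3600))
_CODING_CDS = (201, 3000)
_CODING_LEN = 3600
_CODING_N_CODONS = 300
# engineered codons (1-based codon number -> codon)
_CODING_MOTIFS = {50: "CTT", 51: "GAA", 100: "TGG", 120: "CTT", 192: "GAA"}

# NMD transcript: premature stop 200 bases before the final exon junction
_NMD_EXONS = ((1, 270), (871, 1250), (1751, 2150))
_NMD_CDS = (151, 1050)
_NMD_LEN = 2150
_NMD_N_CODONS = 100
_NMD_MOTIFS = {20: "GAA", 30: "CTT"}

_NONCODING_EXONS = ((1, 300), (1001, 1300))
_NONCODING_LEN = 1300

_KIND_CYCLE = (
    ("coding", "+"),
    ("coding", "-"),
    ("nmd", "+"),
    ("noncoding", "-"),
    ("coding", "+"),
    ("coding", "-"),
    ("nmd", "-"),
    ("noncoding", "+"),
)


def _coding_cds_local(c: int) -> int:
    """Local gene position of coding base c in the coding-gene layout."""
    if c <= 150:
        return 200 + c
    if c <= 450:
        return 1850 + (c - 150)
    return 2550 + (c - 450)


def _nmd_cds_local(c: int) -> int:
    return 150 + c if c <= 120 else 750 + c


@dataclass
class GenePlan:
    """Generator-internal layout of one gene in transcript orientation."""

    index: int
    chrom: str
    strand: str
    start: int  # genomic leftmost base of the gene span
    kind: str  # coding | nmd | noncoding
    local_seq: str  # gene-span sequence on the coding strand
    exons_local: tuple[tuple[int, int], ...]
    cds_local: tuple[int, int] | None

    @property
    def length(self) -> int:
        return len(self.local_seq)

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def gene_id(self) -> str:
        return f"SYNG{self.index:05d}"

    @property
    def gene_symbol(self) -> str:
        return f"Syng{self.index}"

    @property
    def transcript_id(self) -> str:
        return f"SYNT{self.index:05d}"

    def genomic(self, local: int) -> int:
        if self.strand == "+":
            return self.start + local - 1
        return self.start + self.length - local

    def genomic_interval(self, s: int, e: int) -> tuple[int, int]:
        a, b = self.genomic(s), self.genomic(e)
        return (a, b) if a <= b else (b, a)

    def genomic_strand_seq(self) -> str:
        return self.local_seq if self.strand == "+" else reverse_complement(self.local_seq)

    def to_transcript(self) -> TranscriptModel:
        exons = tuple(sorted(self.genomic_interval(s, e) for s, e in self.exons_local))
        if self.cds_local is None:
            cds_start = cds_end = None
            biotype = "lincRNA"
        else:
            cds_start, cds_end = self.genomic_interval(*self.cds_local)
            biotype = NMD_BIOTYPE if self.kind == "nmd" else "protein_coding"
        return TranscriptModel(
            gene_id=self.gene_id,
            gene_symbol=self.gene_symbol,
            transcript_id=self.transcript_id,
            chrom=self.chrom,
            strand=self.strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            biotype=biotype,
        )


@dataclass
class Reference:
    """Synthetic genome plus transcript models (and internal gene plans)."""

    contigs: dict[str, str]
    transcripts: list[TranscriptModel]
    plans: list[GenePlan]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(
    rng: np.random.Generator, n_codons: int, motifs: Mapping[int, str]
) -> str:
    codons = ["ATG"]
    for number in range(2, n_codons):
        codons.append(motifs.get(number, _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]))
    codons.append("TAA")
    return "".join(codons)


def _build_local_seq(rng: np.random.Generator, kind: str) -> str:
    if kind == "coding":
        cds = _random_cds(rng, _CODING_N_CODONS, _CODING_MOTIFS)
        return (
            _random_bases(rng, 200)
            + cds[:150]
            + _random_bases(rng, 1500)
            + cds[150:450]
            + _random_bases(rng, 400)
            + cds[450:900]
            + _random_bases(rng, 600)
        )
    if kind == "nmd":
        cds = _random_cds(rng, _NMD_N_CODONS, _NMD_MOTIFS)
        return (
            _random_bases(rng, 150)
            + cds[:120]
            + _random_bases(rng, 600)
            + cds[120:300]
            + _random_bases(rng, 200)
            + _random_bases(rng, 500)
            + _random_bases(rng, 400)
        )
    return _random_bases(rng, _NONCODING_LEN)


def generate_reference(scenario: SimulationScenario) -> Reference:
    """Build the synthetic genome and transcript models for a scenario.

    Genes are laid out on a fixed pitch so that no variant planted inside or
    near one gene can fall within the annotation flank of another; raises
    when the requested genes cannot be placed on the requested contigs.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    contig_names = [f"chr{i + 1}" for i in range(scenario.n_contigs)]
    arrays = {
        name: list(_random_bases(rng, scenario.contig_length))
        for name in contig_names
    }
    per_contig = -(-scenario.n_genes // scenario.n_contigs)  # ceil
    needed = _FIRST_GENE_OFFSET + (per_contig - 1) * _GENE_PITCH + _CODING_LEN
    if needed > scenario.contig_length:
        raise ValueError(
            f"cannot place {scenario.n_genes} genes with 5 kb flanks on "
            f"{scenario.n_contigs} contig(s) of {scenario.contig_length} bases "
            f"(need >= {needed})"
        )
    plans: list[GenePlan] = []
    for i in range(scenario.n_genes):
        kind, strand = _KIND_CYCLE[i % len(_KIND_CYCLE)]
        chrom = contig_names[i % scenario.n_contigs]
        slot = i // scenario.n_contigs
        start = _FIRST_GENE_OFFSET + slot * _GENE_PITCH + 1
        local_seq = _build_local_seq(rng, kind)
        if kind == "coding":
            exons, cds = _CODING_EXONS, _CODING_CDS
        elif kind == "nmd":
            exons, cds = _NMD_EXONS, _NMD_CDS
        else:
            exons, cds = _NONCODING_EXONS, None
        plan = GenePlan(
            index=i + 1,
            chrom=chrom,
            strand=strand,
            start=start,
            kind=kind,
            local_seq=local_seq,
            exons_local=exons,
            cds_local=cds,
        )
        genomic_seq = plan.genomic_strand_seq()
        arrays[chrom][plan.start - 1 : plan.end] = list(genomic_seq)
        plans.append(plan)
    contigs = {name: "".join(chars) for name, chars in arrays.items()}
    return Reference(
        contigs=contigs,
        transcripts=[p.to_transcript() for p in plans],
        plans=plans,
    )


# ---------------------------------------------------------------------------
# consequence-site registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Site:
    chrom: str
    genomic: int  # SNV: the substituted base; del/dup: the affected base
    kind: str  # snv | del | dup
    alt_coding: str | None  # designed coding-strand alt for engineered SNVs
    strand: str
    transcript_id: str | None
    gene_symbol: str | None


def _plan_sites(plan: GenePlan) -> dict[str, list[_Site]]:
    """All plantable sites of one gene plan, keyed by intended consequence."""

    def snv(local: int, alt: str | None = None) -> _Site:
        return _Site(
            plan.chrom, plan.genomic(local), "snv", alt, plan.strand,
            plan.transcript_id, plan.gene_symbol,
        )

    def flank_site(offset: int, upstream: bool) -> _Site:
        if (plan.strand == "+") == upstream:
            pos = plan.start - offset
        else:
            pos = plan.end + offset
        return _Site(
            plan.chrom, pos, "snv", None, plan.strand,
            plan.transcript_id, plan.gene_symbol,
        )

    sites: dict[str, list[_Site]] = {}
    sites["upstream_gene_variant"] = [
        flank_site(off, True) for off in range(300, 4700, 180)
    ]
    sites["downstream_gene_variant"] = [
        flank_site(off, False) for off in range(300, 4700, 180)
    ]

    if plan.kind == "coding":
        c = _coding_cds_local
        sites["missense_variant"] = [snv(c(574), "A")]  # codon 192 GAA -> AAA
        sites["stop_gained"] = [snv(c(300), "A")]  # codon 100 TGG -> TGA
        sites["stop_lost"] = [snv(c(898), "C")]  # stop TAA -> CAA
        sites["synonymous_variant"] = [snv(c(360), "C")]  # codon 120 CTT -> CTC
        sites["splice_region_variant, synonymous_variant"] = [snv(c(150), "C")]
        sites["missense_variant, splice_region_variant"] = [snv(c(151), "A")]
        if plan.strand == "+":
            sites["frameshift_variant"] = [
                _Site(plan.chrom, plan.genomic(c(200)), "del", None, "+",
                      plan.transcript_id, plan.gene_symbol),
                _Site(plan.chrom, plan.genomic(c(210)), "dup", None, "+",
                      plan.transcript_id, plan.gene_symbol),
            ]
        sites["intron_variant"] = [
            snv(350 + off) for off in range(20, 1480, 23)
        ] + [snv(2150 + off) for off in range(15, 390, 21)]
        sites["5_prime_UTR_variant"] = [snv(p) for p in range(10, 191, 9)]
        sites["3_prime_UTR_variant"] = [snv(p) for p in range(3010, 3591, 11)]
    elif plan.kind == "nmd":
        c = _nmd_cds_local
        sites["synonymous_variant, NMD_transcript_variant"] = [snv(c(90), "C")]
        sites["missense_variant, NMD_transcript_variant"] = [snv(c(58), "A")]
        sites["intron_variant, NMD_transcript_variant"] = [
            snv(270 + off) for off in range(15, 580, 19)
        ] + [snv(1250 + off) for off in range(15, 480, 19)]
        sites["3_prime_UTR_variant, NMD_transcript_variant"] = [
            snv(p) for p in range(1060, 1241, 13)
        ] + [snv(p) for p in range(1760, 2141, 17)]
        sites["splice_region_variant, 3_prime_UTR_variant, NMD_transcript_variant"] = [
            snv(1250), snv(1249), snv(1248)
        ]
    else:  # noncoding
        sites["non_coding_transcript_exon_variant"] = [
            snv(p) for p in range(10, 291, 13)
        ] + [snv(p) for p in range(1010, 1291, 17)]
        sites["intron_variant, non_coding_transcript_variant"] = [
            snv(300 + off) for off in range(15, 680, 17)
        ]
    return sites


def _intergenic_sites(reference: Reference) -> list[_Site]:
    sites: list[_Site] = []
    for chrom, seq in reference.contigs.items():
        spans = sorted(
            (p.start, p.end) for p in reference.plans if p.chrom == chrom
        )
        gaps: list[tuple[int, int]] = []
        prev_end = 0
        for start, end in spans:
            gaps.append((prev_end, start))
            prev_end = end
        gaps.append((prev_end, len(seq) + 1))
        for prev_end, next_start in gaps:
            lo = prev_end + _FLANK + 501
            hi = next_start - _FLANK - 501
            for pos in range(lo, hi, 997):
                sites.append(_Site(chrom, pos, "snv", None, "+", None, None))
    return sites


def _build_registry(reference: Reference) -> dict[str, deque[_Site]]:
    registry: dict[str, deque[_Site]] = {c: deque() for c in TABLE2_COMBINATIONS}
    for plan in reference.plans:
        for combo, sites in _plan_sites(plan).items():
            registry.setdefault(combo, deque()).extend(sites)
    registry["intergenic_variant"].extend(_intergenic_sites(reference))
    return registry


def _site_to_variant(site: _Site, contigs: Mapping[str, str]) -> Variant:
    seq = contigs[site.chrom]
    if site.kind == "snv":
        ref = seq[site.genomic - 1]
        if site.alt_coding is not None:
            alt = (
                site.alt_coding
                if site.strand == "+"
                else reverse_complement(site.alt_coding)
            )
        else:
            alt = _TRANSITION[ref]
        return Variant(site.chrom, site.genomic, ref, alt)
    if site.kind == "del":
        anchor = site.genomic - 1
        return Variant(
            site.chrom, anchor, seq[anchor - 1 : anchor + 1], seq[anchor - 1]
        )
    # dup: insert a copy of the affected base after itself
    base = seq[site.genomic - 1]
    return Variant(site.chrom, site.genomic, base, base + base)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """One row per planted variant: locus, alleles, intended consequence per
    target transcript, intended strain subset and intended filter fate."""

    frame: pd.DataFrame

    _COLUMNS = (
        "variant_id", "chrom", "pos", "ref", "alt", "block", "strains",
        "fate", "consequence", "transcript_id", "gene_symbol", "covered",
        "partition",
    )

    def pass_variants(self) -> list[Variant]:
        rows = self.frame[self.frame.fate == FATE_PASS]
        return [
            Variant(r.chrom, int(r.pos), r.ref, r.alt) for r in rows.itertuples()
        ]

    def pass_keys(self) -> set[tuple[str, int, str]]:
        return {v.key for v in self.pass_variants()}

    def strain_subset(self, variant: Variant) -> frozenset[str]:
        row = self._row(variant)
        return frozenset(row.strains.split(";"))

    def expected_partition(self, variant: Variant) -> str:
        return self._row(variant).partition

    def _row(self, variant: Variant):
        mask = (
            (self.frame.chrom == variant.chrom)
            & (self.frame.pos == variant.pos)
            & (self.frame.alt == variant.alt)
        )
        matches = self.frame[mask]
        if len(matches) != 1:
            raise KeyError(f"no unique truth row for {variant}")
        return next(matches.itertuples())

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        frame = pd.read_csv(
            path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
            na_values=[],
        )
        frame["pos"] = frame["pos"].astype(int)
        frame["covered"] = frame["covered"].astype(str).str.lower() == "true"
        return cls(frame)


def _expected_partition(
    strains: Sequence[str], categories: Mapping[str, str], covered: bool
) -> str:
    if not covered:
        return LABEL_EXCLUSIVE
    cats = {categories[s] for s in strains if categories[s] != CATEGORY_FOCAL}
    if CATEGORY_NORMOTENSIVE in cats or CATEGORY_OTHER in cats:
        return LABEL_CONTROL
    if CATEGORY_HYPERTENSIVE in cats:
        return LABEL_HYPERTENSIVE
    return LABEL_EXCLUSIVE


# ---------------------------------------------------------------------------
# panel + truth generation
# ---------------------------------------------------------------------------

def generate_strain_panel(
    reference: Reference, scenario: SimulationScenario
) -> tuple[StrainPanel, TruthTable]:
    """Plant the sharing blocks onto the reference and build the panel.

    Returns the multi-strain panel (including the focal strain's genotype
    column) and the truth table. Panel loci are the planted *pass* variants
    plus block-structured background loci; every panel strain is fully
    homozygous, and the coverage mask marks the loci inside the focal
    transcriptome (all planted loci, plus ``coverage_fraction`` of the
    background; a coverage_fraction of 0 marks nothing as sequenced).
    """
    rng = np.random.default_rng([scenario.seed, 2])
    registry = _build_registry(reference)
    categories = scenario.categories
    focal = scenario.focal_strain
    panel_strains = scenario.panel_strains

    # --- assign a consequence site to every planted variant ---------------
    combo_first_pass = [c for c in TABLE2_COMBINATIONS if registry.get(c)]
    filler_index = 0
    truth_rows: list[dict] = []
    used_positions: set[tuple[str, int]] = set()
    variant_counter = 0

    def next_site(fate: str) -> tuple[str, _Site]:
        nonlocal filler_index
        if fate == FATE_PASS and combo_first_pass:
            combo = combo_first_pass.pop(0)
            return combo, registry[combo].popleft()
        for _ in range(len(_FILLER_CYCLE) + 1):
            combo = _FILLER_CYCLE[filler_index % len(_FILLER_CYCLE)]
            filler_index += 1
            if registry.get(combo):
                return combo, registry[combo].popleft()
        raise ValueError("placement failure: no free consequence sites left")

    covered_planted = scenario.coverage_fraction > 0
    for block in scenario.sharing_blocks:
        label = block.label or ",".join(block.strains)
        for _ in range(block.n_variants):
            combo, site = next_site(block.fate)
            variant = _site_to_variant(site, reference.contigs)
            if (variant.chrom, variant.pos) in used_positions:
                raise ValueError(
                    f"duplicate planted position {variant.chrom}:{variant.pos}"
                )
            used_positions.add((variant.chrom, variant.pos))
            variant_counter += 1
            truth_rows.append(
                {
                    "variant_id": f"v{variant_counter:04d}",
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "block": label,
                    "strains": ";".join(block.strains),
                    "fate": block.fate,
                    "consequence": combo,
                    "transcript_id": site.transcript_id or "",
                    "gene_symbol": site.gene_symbol or "",
                    "covered": covered_planted,
                    "partition": _expected_partition(
                        block.strains, categories, covered_planted
                    ),
                }
            )
    truth = TruthTable(pd.DataFrame(truth_rows, columns=list(TruthTable._COLUMNS)))

    # --- background loci: block-structured panel-only variation ------------
    clade = [s for s in SHR_CLADE if s in panel_strains]
    sister = SISTER_STRAIN if SISTER_STRAIN in panel_strains else None
    n_bg = scenario.n_background_loci
    patterns: list[tuple[str, ...]] = []
    if clade:
        patterns += [tuple(clade)] * int(0.2 * n_bg)
        if "SBH/Ygl" in panel_strains:
            patterns += [tuple(clade) + ("SBH/Ygl",)] * int(0.1 * n_bg)
    if sister:
        patterns += [(sister,)] * min(3, n_bg)
    others = [s for s in panel_strains if s not in clade and s != sister]
    i = 0
    while len(patterns) < n_bg and others:
        if i % 3 == 2 and len(others) > 1:
            a = others[i % len(others)]
            b = others[(i * 7 + 3) % len(others)]
            patterns.append((a, b) if a != b else (a,))
        else:
            patterns.append((others[i % len(others)],))
        i += 1
    patterns = patterns[:n_bg]

    contig_names = list(reference.contigs)
    background: list[tuple[str, int, str, str, tuple[str, ...]]] = []
    for carriers in patterns:
        while True:
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            pos = int(rng.integers(100, len(reference.contigs[chrom]) - 100))
            if (chrom, pos) not in used_positions:
                break
        used_positions.add((chrom, pos))
        ref = reference.contigs[chrom][pos - 1]
        background.append((chrom, pos, ref, _TRANSITION[ref], carriers))

    # --- genotype matrix ---------------------------------------------------
    all_strains = [focal] + panel_strains
    loci: list[tuple[str, int]] = []
    refs: list[str] = []
    coverage: list[bool] = []
    data: dict[str, list[str | None]] = {s: [] for s in all_strains}

    missing_rate = 0.03
    for row in truth.frame[truth.frame.fate == FATE_PASS].itertuples():
        loci.append((row.chrom, int(row.pos)))
        refs.append(row.ref)
        coverage.append(bool(row.covered))
        carriers = set(row.strains.split(";"))
        for s in all_strains:
            if s == focal or s in carriers:
                data[s].append(row.alt)
            elif rng.random() < missing_rate:
                data[s].append(None)
            else:
                data[s].append(row.ref)
    for chrom, pos, ref, alt, carriers in background:
        loci.append((chrom, pos))
        refs.append(ref)
        coverage.append(bool(rng.random() < scenario.coverage_fraction))
        carrier_set = set(carriers)
        for s in all_strains:
            if s in carrier_set:
                data[s].append(alt)
            elif s != focal and rng.random() < missing_rate:
                data[s].append(None)
            else:
                data[s].append(ref)

    order = np.argsort(
        np.array([f"{c}\x00{p:012d}" for c, p in loci])
    )
    index = pd.MultiIndex.from_tuples(
        [loci[i] for i in order], names=["chrom", "pos"]
    )
    genotypes = pd.DataFrame(
        {s: [data[s][i] for i in order] for s in all_strains},
        index=index,
        dtype=object,
    )
    refs_series = pd.Series([refs[i] for i in order], index=index, name="ref")
    coverage_series = pd.Series([coverage[i] for i in order], index=index)
    panel = StrainPanel(genotypes, refs_series, categories, coverage_series)
    return panel, truth


# ---------------------------------------------------------------------------
# per-animal call sets
# ---------------------------------------------------------------------------

def generate_sample_calls(
    reference: Reference,
    truth: TruthTable,
    scenario: SimulationScenario,
) -> dict[str, list[GenotypeCall]]:
    """Realise per-animal genotype/depth/quality calls for every group.

    Pass-fated variants are homozygous-alt in >= 3 animals with depth >= 10
    in at least one of them and site quality >= 100 in every group; each
    fail fate violates exactly its own criterion in *every* group, so the
    filtered union equals the truth table's pass set by construction.
    Heterozygous noise appears both at planted sites (beyond the three
    guaranteed homozygotes) and at extra noise-only sites.
    """
    rng = np.random.default_rng([scenario.seed, 4])
    model = scenario.read_model
    n_animals = scenario.n_animals_per_group
    p_nb = model.depth_dispersion / (model.depth_dispersion + model.mean_depth)

    def draw_depths(n: int) -> list[int]:
        return [int(d) for d in rng.negative_binomial(model.depth_dispersion, p_nb, n)]

    used = {
        (r.chrom, int(r.pos))
        for r in truth.frame.itertuples()
    }
    noise_sites: list[tuple[str, int, str, str]] = []
    contig_names = list(reference.contigs)
    while len(noise_sites) < scenario.n_noise_sites:
        chrom = contig_names[int(rng.integers(0, len(contig_names)))]
        pos = int(rng.integers(100, len(reference.contigs[chrom]) - 100))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = reference.contigs[chrom][pos - 1]
        noise_sites.append((chrom, pos, ref, _TRANSITION[ref]))

    calls: dict[str, list[GenotypeCall]] = {}
    focal_prefix = scenario.focal_strain.split("/")[0]
    for group in scenario.groups:
        group_calls: list[GenotypeCall] = []
        animals = [f"{focal_prefix}_{group}_{i + 1}" for i in range(n_animals)]
        for row in truth.frame.itertuples():
            fate = row.fate
            depths = draw_depths(n_animals)
            if fate == FATE_PASS:
                gts = [GT_HOM_ALT] * n_animals
                for a in range(3, n_animals):
                    if rng.random() < model.het_noise_rate:
                        gts[a] = GT_HET
                if max(depths[:3]) < 10:
                    depths[0] = 10 + int(rng.integers(0, 15))
                qual = 100.0 + float(np.round(rng.exponential(model.qual_scale)))
            elif fate == FATE_FAIL_HOM:
                gts = [GT_HOM_ALT, GT_HOM_ALT] + [GT_HET] * (n_animals - 2)
                qual = 100.0 + float(np.round(rng.exponential(model.qual_scale)))
            elif fate == FATE_FAIL_DP:
                gts = [GT_HOM_ALT] * n_animals
                depths = [min(d, 9) for d in depths]
                qual = 100.0 + float(np.round(rng.exponential(model.qual_scale)))
            else:  # FATE_FAIL_QUAL
                gts = [GT_HOM_ALT] * n_animals
                depths[0] = max(depths[0], 10)
                qual = float(rng.integers(20, 100))
            for animal, gt, dp in zip(animals, gts, depths):
                group_calls.append(
                    GenotypeCall(
                        sample_id=animal,
                        group_id=group,
                        chrom=row.chrom,
                        pos=int(row.pos),
                        ref=row.ref,
                        alt=row.alt,
                        gt=gt,
                        dp=dp,
                        site_q=qual,
                    )
                )
        for chrom, pos, ref, alt in noise_sites:
            depths = draw_depths(n_animals)
            qual = 100.0 + float(np.round(rng.exponential(model.qual_scale)))
            for a, animal in enumerate(animals):
                gt = GT_HET if rng.random() < 0.4 else GT_HOM_REF
                group_calls.append(
                    GenotypeCall(
                        sample_id=animal,
                        group_id=group,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gt=gt,
                        dp=depths[a],
                        site_q=qual,
                    )
                )
        group_calls.sort(key=lambda c: (c.chrom, c.pos, c.alt, c.sample_id))
        calls[group] = group_calls
    return calls


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_CODES = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1)}


def write_group_vcf(
    path: str | Path,
    group_calls: Sequence[GenotypeCall],
    contig_lengths: Mapping[str, int],
) -> None:
    """One VCF per experimental group: animals as samples, GT + DP, site QUAL."""
    animals = sorted({c.sample_id for c in group_calls})
    header = build_vcf_header(contig_lengths, animals, with_dp=True)
    by_site: dict[tuple[str, int, str, str], dict[str, GenotypeCall]] = {}
    for c in group_calls:
        by_site.setdefault((c.chrom, c.pos, c.ref, c.alt), {})[c.sample_id] = c
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), site in sorted(by_site.items()):
            rec = out.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt)
            )
            rec.qual = next(iter(site.values())).site_q
            for animal in animals:
                call = site[animal]
                sample = rec.samples[animal]
                sample["GT"] = _GT_CODES.get(call.gt, (None, None))
                sample["DP"] = call.dp
            out.write(rec)


def write_panel_vcf(path: str | Path, panel: StrainPanel, contig_lengths: Mapping[str, int]) -> None:
    """Multi-sample VCF of homozygous strain genotypes."""
    header = build_vcf_header(contig_lengths, panel.strains)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos), row in panel.genotypes.iterrows():
            ref = panel.refs.loc[(chrom, pos)]
            alts = sorted(
                {a for a in row.values if a is not None and not pd.isna(a) and a != ref}
            )
            if not alts:
                alts = [_TRANSITION[ref[0]]]  # monomorphic placeholder alt
            alleles = (ref, *alts)
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=alleles)
            for strain in panel.strains:
                allele = row[strain]
                sample = rec.samples[strain]
                if allele is None or pd.isna(allele):
                    sample["GT"] = (None, None)
                else:
                    idx = alleles.index(allele)
                    sample["GT"] = (idx, idx)
            out.write(rec)


def write_strain_categories(path: str | Path, categories: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tcategory\n")
        for strain, category in categories.items():
            fh.write(f"{strain}\t{category}\n")


def write_sample_groups(
    path: str | Path, calls: Mapping[str, Sequence[GenotypeCall]]
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup_id\n")
        seen = set()
        for group, group_calls in calls.items():
            for c in group_calls:
                if c.sample_id not in seen:
                    seen.add(c.sample_id)
                    fh.write(f"{c.sample_id}\t{group}\n")


@dataclass
class SimulationOutput:
    """Paths and in-memory objects produced by :func:`simulate_to_dir`."""

    scenario: SimulationScenario
    reference: Reference
    panel: StrainPanel
    truth: TruthTable
    calls: dict[str, list[GenotypeCall]]
    paths: dict[str, Path]


def simulate_to_dir(scenario: SimulationScenario, outdir: str | Path) -> SimulationOutput:
    """Run the full generator and write every fixture file into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(scenario)
    panel, truth = generate_strain_panel(reference, scenario)
    calls = generate_sample_calls(reference, truth, scenario)

    paths: dict[str, Path] = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "transcripts.gtf",
        "panel_vcf": outdir / "panel.vcf",
        "categories": outdir / "strain_categories.tsv",
        "coverage_bed": outdir / "coverage.bed",
        "truth": outdir / "truth.tsv",
        "groups": outdir / "sample_groups.tsv",
    }
    write_fasta(paths["genome"], reference.contigs)
    write_gtf(paths["gtf"], reference.transcripts)
    write_panel_vcf(paths["panel_vcf"], panel, reference.contig_lengths)
    write_strain_categories(paths["categories"], scenario.categories)
    covered = [
        (chrom, pos)
        for (chrom, pos), ok in panel.coverage.items()
        if ok
    ]
    write_bed_mask(paths["coverage_bed"], covered)
    truth.write_tsv(paths["truth"])
    write_sample_groups(paths["groups"], calls)
    for group, group_calls in calls.items():
        p = outdir / f"calls_{group}.vcf"
        write_group_vcf(p, group_calls, reference.contig_lengths)
        paths[f"calls_{group}"] = p
    return SimulationOutput(scenario, reference, panel, truth, calls, paths)
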