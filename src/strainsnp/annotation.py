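"""Per-transcript consequence calling, impact tiers and SIFT classification.

Each variant is classified against every transcript whose span (plus a
5,000-bp flank by default) contains it, using Sequence Ontology terms:
coding substitutions are resolved by comparing reference and alternate
codons on the coding strand, 1-bp coding indels are frameshifts, positions
within 3 bases of an intron-adjoining exon end or within 8 bases inside an
intron gain ``splice_region_variant`` (splice donor/acceptor bases are
reported under the same term), and transcripts flagged as targets of
nonsense-mediated decay append ``NMD_transcript_variant``. SIFT scores are
external inputs and are only thresholded here (<= 0.05 deleterious).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .hgvs import hgvs_c
from .transcripts import (
    REGION_UTR3,
    REGION_UTR5,
    TranscriptModel,
    reverse_complement,
)
from .variants import Variant

IMPACT_HIGH = "HIGH"
IMPACT_MODERATE = "MODERATE"
IMPACT_LOW = "LOW"
IMPACT_MODIFIER = "MODIFIER"

#: impact tier per SO term; the tier of a term combination is the most severe
IMPACT_BY_TERM: dict[str, str] = {
    "frameshift_variant": IMPACT_HIGH,
    "stop_gained": IMPACT_HIGH,
    "stop_lost": IMPACT_HIGH,
    "missense_variant": IMPACT_MODERATE,
    "splice_region_variant": IMPACT_LOW,
    "synonymous_variant": IMPACT_LOW,
    "5_prime_UTR_variant": IMPACT_MODIFIER,
    "3_prime_UTR_variant": IMPACT_MODIFIER,
    "non_coding_transcript_exon_variant": IMPACT_MODIFIER,
    "intron_variant": IMPACT_MODIFIER,
    "non_coding_transcript_variant": IMPACT_MODIFIER,
    "upstream_gene_variant": IMPACT_MODIFIER,
    "downstream_gene_variant": IMPACT_MODIFIER,
    "intergenic_variant": IMPACT_MODIFIER,
    "NMD_transcript_variant": IMPACT_MODIFIER,
}

#: term ordering within a record, most severe first
TERM_ORDER: tuple[str, ...] = (
    "frameshift_variant",
    "stop_gained",
    "stop_lost",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "NMD_transcript_variant",
)

_IMPACT_RANK = {IMPACT_HIGH: 0, IMPACT_MODERATE: 1, IMPACT_LOW: 2, IMPACT_MODIFIER: 3}

SIFT_DELETERIOUS = "deleterious"
SIFT_TOLERATED = "tolerated"

#: exonic bases within this distance of an intron-adjoining exon end are
#: splice-region; intronic bases within SPLICE_INTRON of the exon are too
SPLICE_EXON = 2  # 0-based distance => the last/first 3 exonic bases
SPLICE_INTRON = 8


@dataclass(frozen=True)
class ConsequenceRecord:
    variant: Variant
    transcript_id: str | None
    gene_symbol: str | None
    so_terms: tuple[str, ...]
    impact: str
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    sift_score: float | None = None
    sift_class: str | None = None

    @property
    def consequence(self) -> str:
        """Comma-joined SO term combination (Table-style)."""
        return ", ".join(self.so_terms)


def impact_of(so_terms: Iterable[str]) -> str:
    """Most severe impact tier among the given SO terms."""
    terms = list(so_terms)
    if not terms:
        raise ValueError("empty SO term list")
    unknown = [t for t in terms if t not in IMPACT_BY_TERM]
    if unknown:
        raise ValueError(f"unknown SO terms: {unknown}")
    return min((IMPACT_BY_TERM[t] for t in terms), key=_IMPACT_RANK.__getitem__)


def classify_sift(score: float) -> str:
    """SIFT class: scores of 0-0.05 are deleterious, above that tolerated."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score must be in [0, 1], got {score}")
    return SIFT_DELETERIOUS if score <= 0.05 else SIFT_TOLERATED


def _order_terms(terms: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(set(terms), key=TERM_ORDER.index))


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _coding_snv_terms(
    variant: Variant, tx: TranscriptModel, genome: Mapping[str, str], c: int
) -> tuple[str, str | None]:
    """SO term and protein change for an SNV at coding position ``c``."""
    cds = tx.spliced_cds(genome)
    codon_index = (c - 1) // 3
    within = (c - 1) % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_base = variant.alt if tx.strand == "+" else reverse_complement(variant.alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    protein = f"{_aa3(ref_aa)}{codon_index + 1}{_aa3(alt_aa)}"
    if ref_aa == alt_aa:
        return "synonymous_variant", protein
    if alt_aa == "*":
        return "stop_gained", protein
    if ref_aa == "*":
        return "stop_lost", protein
    return "missense_variant", protein


def annotate(
    variant: Variant,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    flank: int = 5000,
) -> list[ConsequenceRecord]:
    """Classify a variant against every transcript within ``flank`` bases.

    Returns one record per overlapping transcript, or a single
    ``intergenic_variant`` record when no transcript span (+- flank) contains
    the variant. Raises if the variant's reference allele disagrees with the
    genome sequence.
    """
    contig = genome[variant.chrom]
    observed = contig[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed.upper() != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {observed!r}, variant says {variant.ref!r}"
        )

    # the genomic base whose transcript context decides the consequence
    if variant.is_deletion:
        edit_pos = variant.pos + 1
    else:
        edit_pos = variant.pos

    records: list[ConsequenceRecord] = []
    for tx in transcripts:
        if tx.chrom != variant.chrom:
            continue
        if not (tx.start - flank <= edit_pos <= tx.end + flank):
            continue
        terms: list[str] = []
        protein: str | None = None
        if edit_pos < tx.start or edit_pos > tx.end:
            before = edit_pos < tx.start
            upstream = before if tx.strand == "+" else not before
            terms.append("upstream_gene_variant" if upstream else "downstream_gene_variant")
        else:
            intron = tx.intron_context(edit_pos)
            if intron is not None:
                _, d5, d3 = intron
                if min(d5, d3) <= SPLICE_INTRON:
                    terms.append("splice_region_variant")
                terms.append("intron_variant")
                if not tx.is_coding:
                    terms.append("non_coding_transcript_variant")
            else:
                edge = tx.exon_edge_distance(edit_pos)
                if edge is not None and edge <= SPLICE_EXON:
                    terms.append("splice_region_variant")
                if not tx.is_coding:
                    terms.append("non_coding_transcript_exon_variant")
                else:
                    coord = tx.coding_position(edit_pos)
                    if coord.region == REGION_UTR5:
                        terms.append("5_prime_UTR_variant")
                    elif coord.region == REGION_UTR3:
                        terms.append("3_prime_UTR_variant")
                    elif variant.is_snv:
                        term, protein = _coding_snv_terms(
                            variant, tx, genome, coord.anchor
                        )
                        terms.append(term)
                    else:
                        # only 1-bp indels are supported, so a CDS indel always
                        # shifts the reading frame
                        terms.append("frameshift_variant")
        if tx.is_nmd:
            terms.append("NMD_transcript_variant")
        ordered = _order_terms(terms)
        name_c = hgvs_c(variant, tx, genome)
        records.append(
            ConsequenceRecord(
                variant=variant,
                transcript_id=tx.transcript_id,
                gene_symbol=tx.gene_symbol,
                so_terms=ordered,
                impact=impact_of(ordered),
                hgvs_c=name_c,
                hgvs_p=protein,
            )
        )
    if not records:
        records.append(
            ConsequenceRecord(
                variant=variant,
                transcript_id=None,
                gene_symbol=None,
                so_terms=("intergenic_variant",),
                impact=IMPACT_MODIFIER,
            )
        )
    return records


def annotate_all(
    variants: Iterable[Variant],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    flank: int = 5000,
    sift_scores: Mapping[tuple[tuple[str, int, str], str], float] | None = None,
) -> list[ConsequenceRecord]:
    """Annotate many variants; optionally attach externally supplied SIFT
    scores keyed by ((chrom, pos, alt), transcript_id)."""
    out: list[ConsequenceRecord] = []
    for variant in variants:
        for rec in annotate(variant, transcripts, genome, flank=flank):
            if sift_scores is not None and rec.transcript_id is not None:
                score = sift_scores.get((variant.key, rec.transcript_id))
                if score is not None:
                    rec = dataclasses.replace(
                        rec, sift_score=score, sift_class=classify_sift(score)
                    )
            out.append(rec)
    return out


def read_sift_table(
    path: str | Path,
) -> dict[tuple[tuple[str, int, str], str], float]:
    """Read a SIFT score TSV (chrom, pos, alt, transcript_id, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        ((row.chrom, int(row.pos), row.alt), row.transcript_id): float(row.score)
        for row in df.itertuples()
    }


def records_to_frame(records: Sequence[ConsequenceRecord]) -> pd.DataFrame:
    """Flat annotation table (one row per variant x transcript)."""
    return pd.DataFrame(
        {
            "chrom": [r.variant.chrom for r in records],
            "pos": [r.variant.pos for r in records],
            "ref": [r.variant.ref for r in records],
            "alt": [r.variant.alt for r in records],
            "gene": [r.gene_symbol or "" for r in records],
            "transcript_id": [r.transcript_id or "" for r in records],
            "consequence": [r.consequence for r in records],
            "impact": [r.impact for r in records],
            "hgvs_c": [r.hgvs_c or "" for r in records],
            "hgvs_p": [r.hgvs_p or "" for r in records],
            "sift_score": [r.sift_score for r in records],
            "sift_class": [r.sift_class or "" for r in records],
        }
    )
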