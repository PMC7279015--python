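"""Summary tables and candidate-gene prioritisation.

Works over flat annotation/sharing tables (one row per variant or per
variant x transcript) and over the packaged worked-example tables: the
most-common shared SNPs, the transcript-rearranging (high-impact) SNPs, and
the SIFT-deleterious missense SNPs, together with opaque gene-phenotype
flags. Counting units matter here: "variants" are distinct (chrom, pos)
sites, "annotations" are variant x transcript rows; both counters are
exposed because published effect tables mix the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ConsequenceRecord, IMPACT_HIGH, SIFT_DELETERIOUS

PHENOTYPE_FLAGS = ("hypertension", "neurodegenerative", "mental_disorders")


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("strainsnp.data").joinpath(name).open() as fh:
        return pd.read_csv(
            fh, sep="\t", comment="#", dtype={"chrom": str}, keep_default_na=False
        )


def load_most_common_table() -> pd.DataFrame:
    """Worked-example table of SNPs shared with >= 6 hypertensive strains."""
    return _load_packaged("most_common_snps.tsv")


def load_high_impact_table() -> pd.DataFrame:
    """Worked-example table of transcript-rearranging (high-impact) SNPs."""
    return _load_packaged("high_impact_snps.tsv")


def load_deleterious_table() -> pd.DataFrame:
    """Worked-example table of SIFT-deleterious missense SNPs."""
    return _load_packaged("sift_deleterious_snps.tsv")


def load_gene_phenotypes() -> dict[str, frozenset[str]]:
    """Packaged gene -> phenotype-flag sets."""
    df = _load_packaged("gene_phenotypes.tsv")
    return {
        row.gene: frozenset(f for f in row.flags.split(";") if f)
        for row in df.itertuples()
    }


def read_gene_phenotypes(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a user-supplied (gene, flags) TSV; flags are ';'-separated."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return {
        row.gene: frozenset(f for f in str(row.flags).split(";") if f)
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# counters
# ---------------------------------------------------------------------------

def summarize_effect_classes(records: Sequence[ConsequenceRecord]) -> pd.DataFrame:
    """Count annotations per exact SO-term combination.

    Returns columns (consequence, impact, n_annotations, n_variants) ordered
    by impact severity then count; ``n_variants`` counts distinct
    (chrom, pos, alt) per combination, ``n_annotations`` counts rows.
    """
    if not records:
        return pd.DataFrame(
            columns=["consequence", "impact", "n_annotations", "n_variants"]
        )
    df = pd.DataFrame(
        {
            "consequence": [r.consequence for r in records],
            "impact": [r.impact for r in records],
            "key": [r.variant.key for r in records],
        }
    )
    grouped = (
        df.groupby(["consequence", "impact"])
        .agg(n_annotations=("key", "size"), n_variants=("key", "nunique"))
        .reset_index()
    )
    impact_rank = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
    grouped["_rank"] = grouped["impact"].map(impact_rank)
    grouped = grouped.sort_values(
        ["_rank", "n_annotations", "consequence"], ascending=[True, False, True]
    ).drop(columns="_rank")
    return grouped.reset_index(drop=True)


def count_distinct_genes(rows: pd.DataFrame, gene_column: str = "gene") -> int:
    """Number of distinct gene symbols in a table (duplicates ignored)."""
    genes = rows[gene_column]
    return int(genes[genes != ""].nunique())


def count_locus_cluster(
    rows: pd.DataFrame, chrom: str, start: int, end: int,
    gene_column: str = "gene",
) -> int:
    """Distinct genes with at least one listed position on ``chrom`` within
    the closed window [start, end]."""
    if start >= end:
        raise ValueError("start must be < end")
    hit = rows[
        (rows["chrom"].astype(str) == str(chrom))
        & (rows["pos"].astype(int) >= start)
        & (rows["pos"].astype(int) <= end)
    ]
    return count_distinct_genes(hit, gene_column)


def count_distinct_variants(rows: pd.DataFrame) -> int:
    """Distinct (chrom, pos) sites in a table."""
    return int(rows[["chrom", "pos"]].drop_duplicates().shape[0])


def strain_list(cell: str) -> list[str]:
    return [s for s in str(cell).split(";") if s]


def max_sharing_count(
    rows: pd.DataFrame, include_focal: bool = False, focal: str = "OXYS/Icgn"
) -> int:
    """Largest hypertensive-strain sharing count in a table's strain lists.

    With ``include_focal`` the focal strain is added to lists that omit it,
    so the result is the "n out of 13" count of the published convention.
    """
    best = 0
    for cell in rows["strains"]:
        strains = set(strain_list(cell))
        if include_focal:
            strains.add(focal)
        best = max(best, len(strains))
    return best


# ---------------------------------------------------------------------------
# candidate prioritisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRecord:
    """One candidate variant with everything the ranking needs."""

    chrom: str
    pos: int
    alt: str
    gene: str
    n_hypertensive_carriers: int
    impact: str
    sift_class: str | None
    phenotype_flags: frozenset[str]

    @property
    def protein_changing(self) -> bool:
        return self.impact == IMPACT_HIGH or self.sift_class == SIFT_DELETERIOUS

    @property
    def rank_key(self) -> tuple:
        return (
            0 if self.protein_changing else 1,
            -self.n_hypertensive_carriers,
            -len(self.phenotype_flags),
            self.chrom,
            self.pos,
            self.alt,
        )


def prioritize(candidates: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Deterministic total order over candidates.

    Protein-structure/function-changing variants (HIGH impact or
    SIFT-deleterious) come first, then more widely shared variants (number of
    hypertensive carriers, focal included), then variants in genes with more
    phenotype-association flags; ties break by (chrom, pos, alt).
    """
    return sorted(candidates, key=lambda c: c.rank_key)


def candidates_from_tables(
    most_common: pd.DataFrame | None = None,
    deleterious: pd.DataFrame | None = None,
    phenotypes: Mapping[str, frozenset[str]] | None = None,
    focal: str = "OXYS/Icgn",
) -> list[CandidateRecord]:
    """Assemble candidate records from the worked-example tables.

    Variants appearing in the deleterious table are marked
    SIFT-deleterious; sharing counts include the focal strain.
    """
    phenotypes = phenotypes or {}
    deleterious_keys: set[tuple[str, int]] = set()
    if deleterious is not None:
        deleterious_keys = {
            (str(r.chrom), int(r.pos)) for r in deleterious.itertuples()
        }
    out: dict[tuple[str, int, str], CandidateRecord] = {}
    if most_common is not None:
        for r in most_common.itertuples():
            strains = set(strain_list(r.strains)) | {focal}
            key = (str(r.chrom), int(r.pos), r.gene)
            sift = (
                SIFT_DELETERIOUS
                if (str(r.chrom), int(r.pos)) in deleterious_keys
                else None
            )
            impact = {
                "missense_variant": "MODERATE",
                "synonymous_variant": "LOW",
            }.get(r.classification, "MODIFIER")
            out[key] = CandidateRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                alt=r.gene,  # tables carry no alt allele; gene disambiguates
                gene=r.gene,
                n_hypertensive_carriers=len(strains),
                impact=impact,
                sift_class=sift,
                phenotype_flags=phenotypes.get(r.gene, frozenset()),
            )
    if deleterious is not None:
        for r in deleterious.itertuples():
            key = (str(r.chrom), int(r.pos), r.gene)
            if key in out:
                continue
            strains = set(strain_list(r.strains)) | {focal}
            out[key] = CandidateRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                alt=r.gene,
                gene=r.gene,
                n_hypertensive_carriers=len(strains),
                impact="MODERATE",
                sift_class=SIFT_DELETERIOUS,
                phenotype_flags=phenotypes.get(r.gene, frozenset()),
            )
    return prioritize(out.values())


def candidate_report(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Ranked candidate table for TSV export."""
    ranked = prioritize(candidates)
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "gene": [c.gene for c in ranked],
            "chrom": [c.chrom for c in ranked],
            "pos": [c.pos for c in ranked],
            "n_hypertensive_carriers": [
                c.n_hypertensive_carriers for c in ranked
            ],
            "impact": [c.impact for c in ranked],
            "sift_class": [c.sift_class or "" for c in ranked],
            "phenotype_flags": [
                ";".join(sorted(c.phenotype_flags)) for c in ranked
            ],
            "protein_changing": [c.protein_changing for c in ranked],
        }
    )


def sharing_funnel(
    n_total: int,
    partition: tuple[int, int, int],
    n_most_common: int,
    n_high_impact: int,
    n_deleterious: int,
) -> pd.DataFrame:
    """The stage-by-stage variant funnel (total -> control-shared ->
    hypertensive-shared -> most-common -> protein-changing)."""
    control, hypertensive, exclusive = partition
    return pd.DataFrame(
        {
            "stage": [
                "filtered_total",
                "control_shared",
                "hypertensive_shared",
                "focal_exclusive",
                "most_common",
                "high_impact",
                "sift_deleterious",
            ],
            "n_variants": [
                n_total,
                control,
                hypertensive,
                exclusive,
                n_most_common,
                n_high_impact,
                n_deleterious,
            ],
        }
    )
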