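"""Comparison of a focal strain's SNPs against a multi-strain genotype panel.

The panel holds one homozygous genotype per strain per locus (inbred lines),
a per-locus coverage mask marking which loci fall inside the focal strain's
sequenced transcriptome, and a category per strain. Each focal variant is
profiled into the set of panel strains carrying the same alternate allele and
partitioned:

* ``control_shared`` — carried by at least one normotensive or other control
  strain (control sharing dominates any hypertensive sharing);
* ``hypertensive_shared`` — otherwise carried by >= 1 hypertensive strain;
* ``focal_exclusive`` — carried by no panel strain.

When counting how many hypertensive strains share a variant ("n out of 13"),
the focal strain itself is included in the count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .variants import Variant

CATEGORY_FOCAL = "focal"
CATEGORY_HYPERTENSIVE = "hypertensive"
CATEGORY_NORMOTENSIVE = "normotensive_control"
CATEGORY_OTHER = "other_control"
CATEGORIES = (
    CATEGORY_FOCAL,
    CATEGORY_HYPERTENSIVE,
    CATEGORY_NORMOTENSIVE,
    CATEGORY_OTHER,
)

LABEL_CONTROL = "control_shared"
LABEL_HYPERTENSIVE = "hypertensive_shared"
LABEL_EXCLUSIVE = "focal_exclusive"


class StrainPanel:
    """Homozygous genotype matrix over strains x loci with coverage mask.

    Parameters
    ----------
    genotypes : DataFrame
        Index: MultiIndex (chrom, pos); columns: strain names; values: the
        homozygous allele string of that strain at that locus, or NaN/None for
        a missing genotype.
    refs : Series
        Reference allele per locus, aligned with ``genotypes``.
    categories : mapping
        Strain name -> category; must cover every column.
    coverage : Series or None
        Boolean per locus; ``True`` marks loci inside the focal transcriptome.
        Defaults to all-covered.
    """

    def __init__(
        self,
        genotypes: pd.DataFrame,
        refs: pd.Series,
        categories: Mapping[str, str],
        coverage: pd.Series | None = None,
    ) -> None:
        missing = set(genotypes.columns) - set(categories)
        if missing:
            raise ValueError(f"strains without a category: {sorted(missing)}")
        bad = {c for c in categories.values()} - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown strain categories: {sorted(bad)}")
        if coverage is None:
            coverage = pd.Series(True, index=genotypes.index)
        if not genotypes.index.equals(refs.index) or not genotypes.index.equals(
            coverage.index
        ):
            raise ValueError("genotypes, refs and coverage must share one locus index")
        self.genotypes = genotypes
        self.refs = refs
        self.categories = dict(categories)
        self.coverage = coverage.astype(bool)

    # -- basic views -------------------------------------------------------
    @property
    def strains(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_loci(self) -> int:
        return len(self.genotypes)

    def strains_in_category(self, category: str) -> list[str]:
        return [s for s in self.strains if self.categories[s] == category]

    @property
    def focal_strain(self) -> str | None:
        focal = self.strains_in_category(CATEGORY_FOCAL)
        return focal[0] if focal else None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        categories: Mapping[str, str],
        coverage_sites: set[tuple[str, int]] | None = None,
    ) -> "StrainPanel":
        """Build a panel from a multi-sample VCF of homozygous strain calls.

        Heterozygous panel genotypes are treated as missing (inbred strains
        carry one allele); ``coverage_sites`` (1-based) marks covered loci, or
        all loci when omitted.
        """
        rows: list[tuple[str, int]] = []
        refs: list[str] = []
        data: dict[str, list[str | None]] = {}
        with pysam.VariantFile(str(vcf_path)) as vcf:
            samples = list(vcf.header.samples)
            for s in samples:
                data[s] = []
            for rec in vcf:
                alleles = (rec.ref,) + tuple(rec.alts or ())
                rows.append((rec.chrom, rec.pos))
                refs.append(rec.ref)
                for s in samples:
                    gt = rec.samples[s]["GT"]
                    if not gt or any(a is None for a in gt) or len(set(gt)) > 1:
                        data[s].append(None)
                    else:
                        data[s].append(alleles[gt[0]])
        index = pd.MultiIndex.from_tuples(rows, names=["chrom", "pos"])
        genotypes = pd.DataFrame(data, index=index, columns=samples, dtype=object)
        refs_series = pd.Series(refs, index=index, name="ref")
        if coverage_sites is None:
            coverage = pd.Series(True, index=index)
        else:
            coverage = pd.Series(
                [site in coverage_sites for site in index], index=index
            )
        return cls(genotypes, refs_series, categories, coverage)

    def restrict_to_covered(self) -> "StrainPanel":
        """Drop loci outside the focal transcriptome's sequenced regions."""
        keep = self.coverage
        return StrainPanel(
            self.genotypes.loc[keep],
            self.refs.loc[keep],
            self.categories,
            self.coverage.loc[keep],
        )


def read_strain_categories(path: str | Path) -> dict[str, str]:
    """Read a two-column (strain, category) TSV, header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            strain, category = line.split("\t")[:2]
            if strain == "strain":
                continue
            out[strain] = category
    return out


@dataclass(frozen=True)
class SharingProfile:
    """Panel carriage of one focal variant."""

    variant: Variant
    carriers: frozenset[str]
    n_hypertensive_carriers: int  # focal strain included
    partition_label: str


def profile_variant(variant: Variant, panel: StrainPanel) -> SharingProfile:
    """Which panel strains carry the variant's alternate allele, and partition.

    A locus absent from the panel yields an empty carrier set (the variant is
    then focal-exclusive); a present locus whose panel reference allele
    disagrees with the variant's reference is a coordinate-system fault and
    raises. Missing panel genotypes never count as carriage; the panel's own
    focal-category strain (if the panel includes one) is not a panel carrier.
    """
    key = (variant.chrom, variant.pos)
    if key not in panel.genotypes.index:
        carriers: frozenset[str] = frozenset()
    else:
        panel_ref = panel.refs.loc[key]
        if panel_ref != variant.ref:
            raise ValueError(
                f"reference allele mismatch at {variant.chrom}:{variant.pos}: "
                f"variant says {variant.ref}, panel says {panel_ref}"
            )
        row = panel.genotypes.loc[key]
        carriers = frozenset(
            s
            for s in panel.strains
            if panel.categories[s] != CATEGORY_FOCAL and row[s] == variant.alt
        )
    categories = {panel.categories[s] for s in carriers}
    if CATEGORY_NORMOTENSIVE in categories or CATEGORY_OTHER in categories:
        label = LABEL_CONTROL
    elif CATEGORY_HYPERTENSIVE in categories:
        label = LABEL_HYPERTENSIVE
    else:
        label = LABEL_EXCLUSIVE
    n_hyp = 1 + sum(
        1 for s in carriers if panel.categories[s] == CATEGORY_HYPERTENSIVE
    )
    return SharingProfile(variant, carriers, n_hyp, label)


def profile_variants(
    variants: Iterable[Variant], panel: StrainPanel
) -> list[SharingProfile]:
    return [profile_variant(v, panel) for v in variants]


def partition_counts(profiles: Iterable[SharingProfile]) -> tuple[int, int, int]:
    """(n_control_shared, n_hypertensive_shared, n_focal_exclusive)."""
    counts = Counter(p.partition_label for p in profiles)
    return (
        counts.get(LABEL_CONTROL, 0),
        counts.get(LABEL_HYPERTENSIVE, 0),
        counts.get(LABEL_EXCLUSIVE, 0),
    )


def combination_counts(
    profiles: Iterable[SharingProfile],
    panel: StrainPanel,
    include_focal: bool = True,
) -> dict[frozenset[str], int]:
    """Exact-subset (UpSet-style) counts over hypertensive-shared profiles.

    Keys are the exact sets of hypertensive strains carrying each variant,
    with the focal strain's name included by default (a focal variant is by
    definition carried by the focal strain). Values sum to the
    hypertensive-shared partition count.
    """
    focal = panel.focal_strain or CATEGORY_FOCAL
    hypertensive = set(panel.strains_in_category(CATEGORY_HYPERTENSIVE))
    out: Counter[frozenset[str]] = Counter()
    for p in profiles:
        if p.partition_label != LABEL_HYPERTENSIVE:
            continue
        subset = {s for s in p.carriers if s in hypertensive}
        if include_focal:
            subset.add(focal)
        out[frozenset(subset)] += 1
    return dict(out)


def select_most_common(
    profiles: Iterable[SharingProfile], min_strains: int = 6
) -> list[SharingProfile]:
    """Hypertensive-shared variants carried by >= ``min_strains`` hypertensive
    strains (focal strain included in the count), sorted by carrier count
    descending then locus."""
    if min_strains < 1:
        raise ValueError("min_strains must be >= 1")
    selected = [
        p
        for p in profiles
        if p.partition_label == LABEL_HYPERTENSIVE
        and p.n_hypertensive_carriers >= min_strains
    ]
    selected.sort(key=lambda p: (-p.n_hypertensive_carriers, p.variant.key))
    return selected


def profiles_to_frame(profiles: Sequence[SharingProfile]) -> pd.DataFrame:
    """Flat table of sharing profiles for TSV export."""
    return pd.DataFrame(
        {
            "chrom": [p.variant.chrom for p in profiles],
            "pos": [p.variant.pos for p in profiles],
            "ref": [p.variant.ref for p in profiles],
            "alt": [p.variant.alt for p in profiles],
            "partition": [p.partition_label for p in profiles],
            "n_hypertensive_carriers": [
                p.n_hypertensive_carriers for p in profiles
            ],
            "carriers": [",".join(sorted(p.carriers)) for p in profiles],
        }
    )
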