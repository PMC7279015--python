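"""Homozygosity / depth / quality filtering of per-animal variant calls.

Transcriptome variant calls from individual animals are reduced to a
strain-level SNP list: a site is accepted for an experimental group when the
site quality reaches the floor (default 100), at least ``min_hom`` animals of
the group are homozygous for the *same* alternate allele (default 3), and at
least one of those homozygous animals has read depth >= ``min_dp`` (default
10). Group-level lists are then united across tissue/age groups.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .variants import Variant

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One animal's call at one decomposed (single-alt) variant site."""

    sample_id: str
    group_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str  # hom_ref | het | hom_alt | missing, w.r.t. this alt allele
    dp: int
    site_q: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.dp < 0:
            raise ValueError("dp must be >= 0")
        if self.gt not in (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING):
            raise ValueError(f"unknown genotype state {self.gt!r}")


@dataclass(frozen=True)
class FilteredVariant:
    """A variant accepted for at least one experimental group."""

    chrom: str
    pos: int
    ref: str
    alt: str
    supporting_groups: frozenset[str] = frozenset()
    n_supporting_samples: Mapping[str, int] = field(default_factory=dict)

    @property
    def variant(self) -> Variant:
        return Variant(self.chrom, self.pos, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


def _classify_gt(allele_indices: Sequence[int | None], alt_index: int) -> str:
    """Genotype state of one sample with respect to one alternate allele."""
    if not allele_indices or any(a is None for a in allele_indices):
        return GT_MISSING
    n_alt = sum(1 for a in allele_indices if a == alt_index)
    if n_alt == len(allele_indices):
        return GT_HOM_ALT
    if n_alt > 0:
        return GT_HET
    return GT_HOM_REF


def read_group_calls(
    vcf_path: str | Path,
    group_id: str,
    sample_groups: Mapping[str, str] | None = None,
) -> list[GenotypeCall]:
    """Read per-animal calls from one group's VCF.

    Multiallelic records are decomposed into one :class:`GenotypeCall` per
    sample per alternate allele, so all downstream logic is allele-specific.
    ``sample_groups`` optionally re-maps sample ids to groups; by default every
    sample in the file belongs to ``group_id``.
    """
    calls: list[GenotypeCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                for sample_id, sample in rec.samples.items():
                    group = (
                        sample_groups.get(sample_id, group_id)
                        if sample_groups
                        else group_id
                    )
                    dp = sample.get("DP")
                    calls.append(
                        GenotypeCall(
                            sample_id=sample_id,
                            group_id=group,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gt=_classify_gt(sample["GT"], alt_index),
                            dp=int(dp) if dp is not None else 0,
                            site_q=qual,
                        )
                    )
    return calls


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group_id) TSV, header optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample_id, group = line.split("\t")[:2]
            if sample_id == "sample_id":
                continue
            mapping[sample_id] = group
    return mapping


def filter_group(
    calls: Iterable[GenotypeCall],
    group_id: str,
    min_q: float = 100.0,
    min_dp: int = 10,
    min_hom: int = 3,
) -> list[FilteredVariant]:
    """Apply the strain-level acceptance rules to one experimental group.

    A (chrom, pos, ref, alt) site passes iff its site quality is >= ``min_q``,
    at least ``min_hom`` animals of the group are homozygous for that alt
    allele, and at least one of those homozygous animals has depth >=
    ``min_dp``. The result is sorted by (chrom, pos, alt).
    """
    if min(min_q, min_dp, min_hom) < 0:
        raise ValueError("thresholds must be >= 0")
    by_site: dict[tuple[str, int, str, str], list[GenotypeCall]] = defaultdict(list)
    seen_groups: set[str] = set()
    for call in calls:
        seen_groups.add(call.group_id)
        if call.group_id == group_id:
            by_site[(call.chrom, call.pos, call.ref, call.alt)].append(call)
    if group_id not in seen_groups:
        raise KeyError(f"unknown group_id {group_id!r}")

    passed: list[FilteredVariant] = []
    for (chrom, pos, ref, alt), site_calls in by_site.items():
        site_q = max(c.site_q for c in site_calls)
        if site_q < min_q:
            continue
        hom = [c for c in site_calls if c.gt == GT_HOM_ALT]
        if len(hom) < min_hom:
            continue
        if not any(c.dp >= min_dp for c in hom):
            continue
        passed.append(
            FilteredVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                supporting_groups=frozenset([group_id]),
                n_supporting_samples={group_id: len(hom)},
            )
        )
    passed.sort(key=lambda v: v.key)
    return passed


def union_across_groups(
    per_group_sets: Iterable[Iterable[FilteredVariant]],
) -> list[FilteredVariant]:
    """Merge group-level pass sets into one list keyed by (chrom, pos, alt).

    Supporting groups and per-group sample counts are merged; the same site
    with conflicting alt alleles in different groups stays as distinct
    variants. Idempotent: re-merging the output changes nothing.
    """
    merged: dict[tuple[str, int, str], FilteredVariant] = {}
    for group_set in per_group_sets:
        for fv in group_set:
            existing = merged.get(fv.key)
            if existing is None:
                merged[fv.key] = replace(
                    fv, n_supporting_samples=dict(fv.n_supporting_samples)
                )
            else:
                if existing.ref != fv.ref:
                    raise ValueError(
                        f"ref mismatch at {fv.chrom}:{fv.pos} "
                        f"({existing.ref} vs {fv.ref})"
                    )
                counts = dict(existing.n_supporting_samples)
                for group, n in fv.n_supporting_samples.items():
                    counts[group] = max(counts.get(group, 0), n)
                merged[fv.key] = replace(
                    existing,
                    supporting_groups=existing.supporting_groups
                    | fv.supporting_groups,
                    n_supporting_samples=counts,
                )
    return sorted(merged.values(), key=lambda v: v.key)


def write_filtered_vcf(
    path: str | Path,
    variants: Sequence[FilteredVariant],
    contigs: Mapping[str, int],
) -> None:
    """Write the united filtered list as a sites-only VCF."""
    from .io import build_vcf_header

    header = build_vcf_header(contigs)
    header.info.add("GROUPS", ".", "String", "Supporting experimental groups")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for fv in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = out.new_record(
                contig=fv.chrom, start=fv.pos - 1, alleles=(fv.ref, fv.alt)
            )
            if fv.supporting_groups:
                rec.info["GROUPS"] = ",".join(sorted(fv.supporting_groups))
            out.write(rec)
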