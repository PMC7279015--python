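"""Minimal variant representation shared by all pipeline stages.

Coordinates are 1-based and fully closed throughout, matching VCF and GTF
conventions. Alleles are stored VCF-style: a single-base substitution has
``len(ref) == len(alt) == 1``; a 1-bp deletion is ``ref="AB", alt="A"``
anchored at the base before the deleted one; a 1-bp insertion is
``ref="A", alt="AB"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

_BASES = set("ACGT")


@total_ordering
@dataclass(frozen=True)
class Variant:
    """One alternate allele at one genomic site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")
        if abs(len(self.ref) - len(self.alt)) > 1 or max(len(self.ref), len(self.alt)) > 2:
            raise ValueError(
                "only single-nucleotide and length-1 indel alleles are supported: "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    # -- allele class ------------------------------------------------------
    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) == len(self.ref) + 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) == len(self.alt) + 1

    @property
    def indel_length(self) -> int:
        """Signed length change (+1 insertion, -1 deletion, 0 SNV)."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used for set semantics: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)

    def __lt__(self, other: "Variant") -> bool:
        return (self.chrom, self.pos, self.alt) < (other.chrom, other.pos, other.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"
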