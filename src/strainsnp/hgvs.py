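"""HGVS coding-DNA ("c.") descriptions for SNVs and 1-bp indels.

Coding positions are numbered 1..n from the A of the start codon; 5' UTR
positions are negative (c.-12), 3' UTR positions count past the last base of
the stop codon with a star (c.*57), and intronic positions anchor to the
nearest exon boundary with a +/- offset (c.164+134, c.1148-981). Alleles are
written on the coding strand with no whitespace (c.574G>A); the typography
"c.574G > A" seen in print is accepted on parsing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .transcripts import CodingCoordinate, TranscriptModel
from .variants import Variant

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class HgvsC:
    """Parsed c. description."""

    kind: str  # sub | del | dup | ins
    anchor: str  # e.g. "574", "-12", "*57", "164+134"
    ref: str | None = None
    alt: str | None = None
    anchor2: str | None = None  # second anchor for ins

    def __str__(self) -> str:
        if self.kind == "sub":
            return f"c.{self.anchor}{self.ref}>{self.alt}"
        if self.kind == "del":
            return f"c.{self.anchor}del"
        if self.kind == "dup":
            return f"c.{self.anchor}dup"
        return f"c.{self.anchor}_{self.anchor2}ins{self.alt}"


_POS = r"(\*?-?\d+(?:[+-]\d+)?)"
_RE_SUB = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_RE_DEL = re.compile(rf"^c\.{_POS}del$")
_RE_DUP = re.compile(rf"^c\.{_POS}dup$")
_RE_INS = re.compile(rf"^c\.{_POS}_{_POS}ins([ACGT]+)$")


def parse_hgvs_c(text: str) -> HgvsC:
    """Parse a c. description (whitespace-tolerant)."""
    compact = re.sub(r"\s+", "", text)
    if m := _RE_SUB.match(compact):
        return HgvsC("sub", m.group(1), ref=m.group(2), alt=m.group(3))
    if m := _RE_DEL.match(compact):
        return HgvsC("del", m.group(1))
    if m := _RE_DUP.match(compact):
        return HgvsC("dup", m.group(1))
    if m := _RE_INS.match(compact):
        return HgvsC("ins", m.group(1), anchor2=m.group(2), alt=m.group(3))
    raise ValueError(f"cannot parse HGVS c. description {text!r}")


def _coordinate_label(tx: TranscriptModel, pos: int) -> str:
    """c.-style label of any genomic position inside the transcript span."""
    coord = tx.coding_position(pos)
    if coord is not None:
        return coord.label
    intron = tx.intron_context(pos)
    if intron is None:
        raise ValueError(f"{pos} lies outside transcript {tx.transcript_id}")
    j, d5, d3 = intron
    exons = tx.exons_tx_order
    if d5 <= d3:
        # anchor on the 3' end of the upstream exon
        edge = exons[j][1] if tx.strand == "+" else exons[j][0]
        base = tx.coding_position(edge)
        return CodingCoordinate(base.region, base.anchor, d5).label
    edge = exons[j + 1][0] if tx.strand == "+" else exons[j + 1][1]
    base = tx.coding_position(edge)
    return CodingCoordinate(base.region, base.anchor, -d3).label


def hgvs_c(
    variant: Variant,
    tx: TranscriptModel,
    genome: Mapping[str, str] | None = None,
) -> str | None:
    """Format a variant as a c. description on ``tx``'s coding strand.

    Returns None for non-coding transcripts and for variants outside the
    transcript span (up/downstream variants have no c. name). ``genome`` is
    only needed to recognise a 1-bp insertion as a duplication.
    """
    if not tx.is_coding or variant.chrom != tx.chrom:
        return None

    if variant.is_snv:
        if not (tx.start <= variant.pos <= tx.end):
            return None
        label = _coordinate_label(tx, variant.pos)
        ref, alt = variant.ref, variant.alt
        if tx.strand == "-":
            ref, alt = _COMP[ref], _COMP[alt]
        return str(HgvsC("sub", label, ref=ref, alt=alt))

    if variant.is_deletion:
        deleted = variant.pos + 1  # VCF anchors the base before the deletion
        if not (tx.start <= deleted <= tx.end):
            return None
        return str(HgvsC("del", _coordinate_label(tx, deleted)))

    # 1-bp insertion between genomic variant.pos and variant.pos + 1
    if not (tx.start <= variant.pos <= tx.end and tx.start <= variant.pos + 1 <= tx.end):
        return None
    inserted = variant.alt[-1]
    if tx.strand == "+":
        five_prime, three_prime = variant.pos, variant.pos + 1
        coding_insert = inserted
    else:
        five_prime, three_prime = variant.pos + 1, variant.pos
        coding_insert = _COMP[inserted]
    if genome is not None:
        neighbour = genome[tx.chrom][five_prime - 1]
        coding_neighbour = neighbour if tx.strand == "+" else _COMP[neighbour]
        if coding_neighbour == coding_insert:
            return str(HgvsC("dup", _coordinate_label(tx, five_prime)))
    return str(
        HgvsC(
            "ins",
            _coordinate_label(tx, five_prime),
            anchor2=_coordinate_label(tx, three_prime),
            alt=coding_insert,
        )
    )
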