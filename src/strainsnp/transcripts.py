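"""Gene/transcript structures and the coordinate arithmetic behind annotation.

A :class:`TranscriptModel` stores exons as 1-based fully-closed genomic
intervals plus an optional CDS span. The CDS here *includes* the stop codon,
so a valid coding sequence starts with ATG, ends with a stop codon and has a
spliced length divisible by 3. Transcript ("n.") and coding ("c.")
coordinates are derived on the fly; nothing is cached, keeping the objects
trivially picklable and hashable by identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

NMD_BIOTYPE = "nonsense_mediated_decay"

# coding-region classes used by coding_position()
REGION_CDS = "cds"
REGION_UTR5 = "utr5"
REGION_UTR3 = "utr3"


@dataclass(frozen=True)
class CodingCoordinate:
    """A c.-style coordinate: region + anchor within that region.

    ``anchor`` is the coding position (1..n) for CDS, the negative offset for
    the 5' UTR (c.-k) or the positive offset past the stop codon for the
    3' UTR (c.*k). ``offset`` is the intronic +/- offset (0 for exonic)."""

    region: str
    anchor: int
    offset: int = 0

    @property
    def label(self) -> str:
        if self.region == REGION_UTR3:
            base = f"*{self.anchor}"
        else:
            base = str(self.anchor)  # negative anchors already carry the sign
        if self.offset > 0:
            return f"{base}+{self.offset}"
        if self.offset < 0:
            return f"{base}{self.offset}"
        return base


@dataclass(frozen=True, eq=False)
class TranscriptModel:
    gene_id: str
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, sorted, 1-based closed
    cds_start: int | None = None  # genomic leftmost CDS base (incl. stop codon)
    cds_end: int | None = None  # genomic rightmost CDS base
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} must be sorted and disjoint"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be given together")
        if self.is_coding:
            if not (
                self._exon_containing(self.cds_start) is not None
                and self._exon_containing(self.cds_end) is not None
            ):
                raise ValueError("CDS boundaries must lie inside exons")
            if self.cds_length % 3 != 0:
                raise ValueError(
                    f"spliced CDS length of {self.transcript_id} is "
                    f"{self.cds_length}, not a multiple of 3"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def is_nmd(self) -> bool:
        return self.biotype == NMD_BIOTYPE

    @property
    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (reversed for the minus strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def _exon_containing(self, pos: int) -> int | None:
        """Genomic-order exon index containing ``pos``, or None."""
        for i, (start, end) in enumerate(self.exons):
            if start <= pos <= end:
                return i
        return None

    # -- transcript coordinates -------------------------------------------
    def tx_position(self, pos: int) -> int | None:
        """1-based position within the spliced transcript, or None (intron)."""
        offset = 0
        for start, end in self.exons_tx_order:
            if start <= pos <= end:
                return offset + (pos - start + 1 if self.strand == "+" else end - pos + 1)
            offset += end - start + 1
        return None

    @property
    def tx_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def cds_tx_span(self) -> tuple[int, int]:
        """(tx position of first coding base, tx position of last stop base)."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        first = self.cds_start if self.strand == "+" else self.cds_end
        last = self.cds_end if self.strand == "+" else self.cds_start
        return self.tx_position(first), self.tx_position(last)

    @property
    def cds_length(self) -> int:
        lo, hi = sorted((self.cds_start, self.cds_end))
        return sum(
            max(0, min(end, hi) - max(start, lo) + 1) for start, end in self.exons
        )

    def coding_position(self, pos: int) -> CodingCoordinate | None:
        """HGVS-style c. coordinate of an exonic genomic position.

        Returns None for intronic positions (see :meth:`intron_context`) and
        raises for non-coding transcripts.
        """
        n = self.tx_position(pos)
        if n is None:
            return None
        cds_lo, cds_hi = self.cds_tx_span
        # the stop codon occupies the last 3 coding positions; positions past
        # it are 3' UTR (*k)
        if n < cds_lo:
            return CodingCoordinate(REGION_UTR5, n - cds_lo)
        if n > cds_hi:
            return CodingCoordinate(REGION_UTR3, n - cds_hi)
        return CodingCoordinate(REGION_CDS, n - cds_lo + 1)

    def intron_context(self, pos: int) -> tuple[int, int, int] | None:
        """For an intronic position: (tx intron index, d5, d3).

        ``d5`` is the 1-based distance into the intron from the upstream
        (transcript 5') exon, ``d3`` the distance to the downstream exon.
        Returns None for exonic or out-of-span positions.
        """
        if not (self.start <= pos <= self.end) or self.tx_position(pos) is not None:
            return None
        exons = self.exons_tx_order
        for j in range(len(exons) - 1):
            up, down = exons[j], exons[j + 1]
            if self.strand == "+":
                if up[1] < pos < down[0]:
                    return j, pos - up[1], down[0] - pos
            else:
                if down[1] < pos < up[0]:
                    return j, up[0] - pos, pos - down[1]
        return None

    def exon_edge_distance(self, pos: int) -> int | None:
        """Distance (0-based) from an exonic position to the nearest exon edge
        that adjoins an intron; None if not exonic or single-exon."""
        exons = self.exons_tx_order
        for j, (start, end) in enumerate(exons):
            if not (start <= pos <= end):
                continue
            edge5 = end if self.strand == "-" else start
            edge3 = start if self.strand == "-" else end
            dists = []
            if j > 0:  # 5' edge adjoins an intron
                dists.append(abs(pos - edge5))
            if j < len(exons) - 1:  # 3' edge adjoins an intron
                dists.append(abs(pos - edge3))
            return min(dists) if dists else None
        return None

    # -- sequence ----------------------------------------------------------
    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Full mRNA sequence on the coding strand."""
        contig = genome[self.chrom]
        parts = [contig[start - 1 : end] for start, end in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS (ATG..stop) on the coding strand."""
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        lo, hi = sorted((self.cds_start, self.cds_end))
        contig = genome[self.chrom]
        parts = [
            contig[max(start, lo) - 1 : min(end, hi)]
            for start, end in self.exons
            if min(end, hi) >= max(start, lo)
        ]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GTF input/output
# ---------------------------------------------------------------------------

def write_gtf(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    """Write transcript models as GTF (gene/transcript/exon/CDS features).

    CDS features include the stop codon, mirroring how the models store it.
    """
    def attrs(tx: TranscriptModel, with_tx: bool = True) -> str:
        parts = [f'gene_id "{tx.gene_id}"']
        if with_tx:
            parts.append(f'transcript_id "{tx.transcript_id}"')
        parts.append(f'gene_name "{tx.gene_symbol}"')
        if with_tx:
            parts.append(f'transcript_biotype "{tx.biotype}"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            rows = [("gene", tx.start, tx.end, attrs(tx, with_tx=False)),
                    ("transcript", tx.start, tx.end, attrs(tx))]
            for start, end in tx.exons:
                rows.append(("exon", start, end, attrs(tx)))
            if tx.is_coding:
                lo, hi = sorted((tx.cds_start, tx.cds_end))
                for start, end in tx.exons:
                    s, e = max(start, lo), min(end, hi)
                    if s <= e:
                        rows.append(("CDS", s, e, attrs(tx)))
            for feature, start, end, attr in rows:
                fh.write(
                    f"{tx.chrom}\tstrainsnp\t{feature}\t{start}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attr}\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from a GTF written by :func:`write_gtf` (or any
    GTF carrying gene_id/transcript_id/gene_name/transcript_biotype and CDS
    features that include the stop codon)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        exons = tuple(
            sorted(
                (f.start, f.end)
                for f in db.children(tx, featuretype="exon")
            )
        )
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        out.append(
            TranscriptModel(
                gene_id=tx["gene_id"][0],
                gene_symbol=tx["gene_name"][0] if "gene_name" in tx.attributes else tx["gene_id"][0],
                transcript_id=tx["transcript_id"][0],
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=tx["transcript_biotype"][0]
                if "transcript_biotype" in tx.attributes
                else "protein_coding",
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out
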