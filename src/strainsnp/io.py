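"""Shared file-format helpers (FASTA, VCF headers, BED coverage masks)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a plain chrom -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, contigs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def build_vcf_header(
    contigs: Mapping[str, int],
    samples: Sequence[str] = (),
    with_dp: bool = False,
) -> pysam.VariantHeader:
    """VCF v4.2 header with GT (and optionally per-sample DP) FORMAT fields."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        if with_dp:
            header.formats.add("DP", 1, "Integer", "Read depth")
        for sample in samples:
            header.add_sample(sample)
    return header


def read_bed_mask(path: str | Path) -> set[tuple[str, int]]:
    """Expand a BED file into the set of covered (chrom, 1-based pos) sites.

    BED is half-open 0-based on disk; the returned positions follow the
    package-wide 1-based fully-closed convention.
    """
    covered: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end = line.split("\t")[:3]
            for pos in range(int(start) + 1, int(end) + 1):
                covered.add((chrom, pos))
    return covered


def write_bed_mask(path: str | Path, sites: Iterable[tuple[str, int]]) -> None:
    """Write 1-based sites as single-base BED intervals, merged where adjacent."""
    ordered = sorted(set(sites))
    with open(path, "w") as fh:
        run_start = None
        prev: tuple[str, int] | None = None
        for chrom, pos in ordered:
            if prev is not None and chrom == prev[0] and pos == prev[1] + 1:
                prev = (chrom, pos)
                continue
            if prev is not None:
                fh.write(f"{prev[0]}\t{run_start - 1}\t{prev[1]}\n")
            run_start = pos
            prev = (chrom, pos)
        if prev is not None:
            fh.write(f"{prev[0]}\t{run_start - 1}\t{prev[1]}\n")
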