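"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a result from first principles along a different
code path than the package: the filter oracle applies the three acceptance
rules site by site, the consequence oracle rebuilds the entire mRNA and
protein before and after the edit and diffs them, the UPGMA oracle
re-averages all cluster pair distances at every step, and the IBS oracle
counts allele matches pair by pair.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def brute_force_filter(calls, group_id, min_q=100.0, min_dp=10, min_hom=3):
    """Per-site exhaustive check of the three acceptance rules."""
    sites = defaultdict(list)
    for c in calls:
        if c.group_id == group_id:
            sites[(c.chrom, c.pos, c.ref, c.alt)].append(c)
    passed = set()
    for key, site_calls in sites.items():
        rule_q = any(c.site_q >= min_q for c in site_calls)
        hom = [c for c in site_calls if c.gt == "hom_alt"]
        rule_hom = len(hom) >= min_hom
        rule_dp = any(c.dp >= min_dp for c in hom)
        if rule_q and rule_hom and rule_dp:
            chrom, pos, _, alt = key
            passed.add((chrom, pos, alt))
    return passed


# ---------------------------------------------------------------------------
# consequence calling (full rebuild-and-diff)
# ---------------------------------------------------------------------------

def _tx_pos(tx, pos):
    offset = 0
    exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
    for start, end in exons:
        if start <= pos <= end:
            return offset + (pos - start + 1 if tx.strand == "+" else end - pos + 1)
        offset += end - start + 1
    return None


def _splice_terms(tx, pos):
    """splice_region membership recomputed directly from the exon list."""
    exons = tx.exons
    in_exon = any(s <= pos <= e for s, e in exons)
    if in_exon:
        for i, (s, e) in enumerate(exons):
            if s <= pos <= e:
                dists = []
                if i > 0:
                    dists.append(pos - s)
                if i < len(exons) - 1:
                    dists.append(e - pos)
                return bool(dists) and min(dists) <= 2
    else:
        dists = []
        for i in range(len(exons) - 1):
            if exons[i][1] < pos < exons[i + 1][0]:
                dists = [pos - exons[i][1], exons[i + 1][0] - pos]
        return bool(dists) and min(dists) <= 8
    return False


def rebuild_and_diff(variant, tx, genome, flank=5000):
    """SO terms for one SNV x transcript by full-sequence comparison."""
    assert len(variant.ref) == 1 and len(variant.alt) == 1
    pos = variant.pos
    if variant.chrom != tx.chrom:
        return None
    if not (tx.start - flank <= pos <= tx.end + flank):
        return None
    terms = set()
    if pos < tx.start or pos > tx.end:
        before = pos < tx.start
        upstream = before if tx.strand == "+" else not before
        terms.add("upstream_gene_variant" if upstream else "downstream_gene_variant")
    else:
        edited = dict(genome)
        contig = edited[variant.chrom]
        edited[variant.chrom] = (
            contig[: pos - 1] + variant.alt + contig[pos:]
        )
        in_exon = _tx_pos(tx, pos) is not None
        if _splice_terms(tx, pos):
            terms.add("splice_region_variant")
        if not in_exon:
            terms.add("intron_variant")
            if not tx.is_coding:
                terms.add("non_coding_transcript_variant")
        elif not tx.is_coding:
            terms.add("non_coding_transcript_exon_variant")
        else:
            n = _tx_pos(tx, pos)
            first = tx.cds_start if tx.strand == "+" else tx.cds_end
            last = tx.cds_end if tx.strand == "+" else tx.cds_start
            cds_lo, cds_hi = _tx_pos(tx, first), _tx_pos(tx, last)
            if n < cds_lo:
                terms.add("5_prime_UTR_variant")
            elif n > cds_hi:
                terms.add("3_prime_UTR_variant")
            else:
                ref_p = str(Seq(tx.spliced_cds(genome)).translate())
                alt_p = str(Seq(tx.spliced_cds(edited)).translate())
                if ref_p == alt_p:
                    terms.add("synonymous_variant")
                elif "*" in alt_p[:-1] and "*" not in ref_p[:-1]:
                    terms.add("stop_gained")
                elif ref_p.endswith("*") and not alt_p.endswith("*"):
                    terms.add("stop_lost")
                else:
                    terms.add("missense_variant")
    if tx.is_nmd:
        terms.add("NMD_transcript_variant")
    return terms


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def brute_force_upgma(dist, labels):
    """Naive UPGMA recomputing every cluster-pair average at each step.

    Returns {frozenset(leaves): merge_height} for every internal node.
    """
    dist = np.asarray(dist, float)
    clusters = [frozenset([l]) for l in labels]
    index = {l: i for i, l in enumerate(labels)}
    merges = {}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [
                    dist[index[a], index[b]]
                    for a in clusters[i]
                    for b in clusters[j]
                ]
                d = float(np.mean(pairs))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges[merged] = d / 2.0
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def tree_clades_with_heights(tree):
    """{frozenset(leaves): height} for every internal node of a skbio tree."""
    out = {}
    for node in tree.non_tips(include_self=True):
        leaves = frozenset(t.name for t in node.tips())
        # height = distance from this node down to any tip
        tip = next(iter(node.tips()))
        out[leaves] = node.distance(tip)
    return out


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

def brute_force_ibs(genotypes: pd.DataFrame):
    """Pairwise allele-match fractions via explicit loops."""
    strains = list(genotypes.columns)
    n = len(strains)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            same = 0
            total = 0
            for _, row in genotypes.iterrows():
                a, b = row.iloc[i], row.iloc[j]
                if a is None or b is None or pd.isna(a) or pd.isna(b):
                    continue
                total += 1
                if a == b:
                    same += 1
            out[i, j] = out[j, i] = same / total
    return out
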