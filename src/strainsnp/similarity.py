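"""Inter-strain genetic similarity: IBS matrix, UPGMA dendrogram, classical MDS.

Identity by state between two inbred strains is the fraction of shared
alleles over loci genotyped in both (pairwise-complete handling of missing
genotypes). The dendrogram uses average linkage (UPGMA) on ``1 - IBS``
distances and is ultrametric; leaf heights are half the merge distances.
Classical multidimensional scaling (principal coordinates) embeds the same
distances via eigendecomposition of the double-centred squared-distance
matrix, with axis signs fixed so the largest-magnitude loading on each axis
is positive.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import skbio


@dataclass
class IBSMatrix:
    strains: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]
    n_loci: np.ndarray  # co-genotyped locus count per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.strains)

    @property
    def distances(self) -> np.ndarray:
        """1 - IBS, the conventional IBS distance."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def nearest_neighbor(self, strain: str) -> str:
        """The other strain with the highest IBS to ``strain``."""
        i = self.strains.index(strain)
        row = self.values[i].copy()
        row[i] = -np.inf
        return self.strains[int(np.argmax(row))]


def ibs_matrix(genotypes: pd.DataFrame) -> IBSMatrix:
    """IBS over a loci x strains matrix of homozygous allele strings.

    Missing genotypes (NaN/None) are excluded pair-by-pair; with genotypes
    coded as alt-allele dosage in {0, 2} this equals
    ``mean((2 - |g_i - g_j|) / 2)`` over co-genotyped loci. Raises when fewer
    than two strains are given or some pair shares no genotyped locus.
    """
    strains = list(genotypes.columns)
    if len(strains) < 2:
        raise ValueError("IBS needs at least two strains")
    alleles = genotypes.to_numpy(dtype=object)
    present = ~pd.isna(alleles)
    n = len(strains)
    values = np.eye(n)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = int(present[:, i].sum())
        for j in range(i + 1, n):
            both = present[:, i] & present[:, j]
            n_loci = int(both.sum())
            if n_loci == 0:
                raise ValueError(
                    f"strains {strains[i]!r} and {strains[j]!r} share no "
                    "co-genotyped locus"
                )
            same = float(np.sum(alleles[both, i] == alleles[both, j]))
            values[i, j] = values[j, i] = same / n_loci
            counts[i, j] = counts[j, i] = n_loci
    return IBSMatrix(strains, values, counts)


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return dist


def upgma(dist: np.ndarray, labels: Sequence[str]) -> skbio.TreeNode:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    Returns an ultrametric :class:`skbio.TreeNode`; every leaf sits at depth
    equal to half its cluster's merge distance, so two strains at distance
    ``d`` join at height ``d/2``. Merge heights are non-decreasing.
    """
    dist = _check_distance_matrix(dist)
    if len(labels) != dist.shape[0]:
        raise ValueError("label count must match the distance matrix")
    if len(labels) == 1:
        raise ValueError("cannot build a dendrogram from a single strain")
    linkage = hierarchy.average(squareform(dist, checks=False))
    root = hierarchy.to_tree(linkage)

    def _newick(node) -> tuple[str, float]:
        """Return (subtree newick, node height)."""
        if node.is_leaf():
            return str(labels[node.id]), 0.0
        left, lh = _newick(node.left)
        right, rh = _newick(node.right)
        height = node.dist / 2.0
        return (
            f"({left}:{height - lh:.10g},{right}:{height - rh:.10g})",
            height,
        )

    newick, _ = _newick(root)
    return skbio.TreeNode.read(_io.StringIO(newick + ";"))


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # strains x k axes
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    explained_fraction: np.ndarray  # per retained axis, over positive eigenvalues

    @property
    def stress(self) -> float:
        """Fraction of (squared) variation not captured by the retained axes."""
        positive = np.clip(self.eigenvalues, 0.0, None)
        total = positive.sum()
        if total == 0:
            return 0.0
        k = self.coordinates.shape[1]
        return float(1.0 - positive[:k].sum() / total)


def classical_mds(
    dist: np.ndarray, labels: Sequence[str], k: int = 2
) -> EmbeddingResult:
    """Classical MDS / principal coordinates of a distance matrix.

    Double-centres ``-0.5 * J D^2 J``, takes the top-``k`` eigenvectors scaled
    by the square roots of their (non-negative) eigenvalues, and fixes each
    axis's sign so its largest-magnitude loading is positive. ``k`` must not
    exceed n - 1.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if len(labels) != n:
        raise ValueError("label count must match the distance matrix")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be between 1 and n - 1 = {n - 1}, got {k}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    positive = np.clip(eigvals, 0.0, None)
    total = positive.sum()
    explained = positive[:k] / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(labels), columns=[f"axis{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(frame, eigvals, explained)
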