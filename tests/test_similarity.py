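"""IBS, UPGMA and classical MDS: closed forms, brute-force oracles, and the
sister-strain recovery property on the synthetic panel."""

import numpy as np
import pandas as pd
import pytest
from skbio.stats.ordination import pcoa
from skbio.stats.distance import DistanceMatrix

from oracles import brute_force_ibs, brute_force_upgma, tree_clades_with_heights
from strainsnp.similarity import classical_mds, ibs_matrix, upgma
from strainsnp.simulate import FOCAL_STRAIN, SISTER_STRAIN


def geno(columns):
    return pd.DataFrame(columns, dtype=object)


def test_identical_strains_have_ibs_one():
    g = geno({"a": ["A"] * 10, "b": ["A"] * 10})
    assert ibs_matrix(g).values[0, 1] == 1.0


def test_opposite_homozygotes_have_ibs_zero():
    g = geno({"a": ["A"] * 10, "b": ["G"] * 10})
    assert ibs_matrix(g).values[0, 1] == 0.0


def test_hand_counted_ibs():
    # 6 concordant + 4 discordant homozygous pairs -> IBS 0.6
    g = geno({"a": ["A"] * 10, "b": ["A"] * 6 + ["G"] * 4})
    assert ibs_matrix(g).values[0, 1] == pytest.approx(0.6)


def test_missing_genotypes_use_pairwise_complete_loci():
    g = geno({"a": ["A", "A", None, "A"], "b": ["A", None, "G", "G"]})
    ibs = ibs_matrix(g)
    assert ibs.n_loci[0, 1] == 2
    assert ibs.values[0, 1] == pytest.approx(0.5)


def test_single_strain_and_zero_locus_pairs_are_errors():
    with pytest.raises(ValueError):
        ibs_matrix(geno({"a": ["A"]}))
    with pytest.raises(ValueError, match="no co-genotyped"):
        ibs_matrix(geno({"a": ["A", None], "b": [None, "G"]}))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ibs_matches_brute_force_counting(seed):
    rng = np.random.default_rng(seed)
    alleles = np.array(["A", "C", "G", "T", None], dtype=object)
    g = pd.DataFrame(
        {f"s{i}": alleles[rng.integers(0, 5, 50)] for i in range(6)},
        dtype=object,
    )
    # avoid all-missing pairs
    g.iloc[0] = "A"
    ibs = ibs_matrix(g)
    np.testing.assert_allclose(ibs.values, brute_force_ibs(g), atol=1e-12)


def test_two_strains_join_at_half_their_distance():
    d = np.array([[0.0, 0.4], [0.4, 0.0]])
    tree = upgma(d, ["a", "b"])
    heights = tree_clades_with_heights(tree)
    assert heights[frozenset({"a", "b"})] == pytest.approx(0.2)


def test_block_structure_gives_block_topology():
    labels = ["A", "B", "C", "D"]
    d = np.full((4, 4), 0.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    tree = upgma(d, labels)
    clades = {c for c in tree_clades_with_heights(tree)}
    assert frozenset({"A", "B"}) in clades
    assert frozenset({"C", "D"}) in clades


def test_non_symmetric_distances_are_rejected():
    d = np.array([[0.0, 0.5], [0.4, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        upgma(d, ["a", "b"])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_upgma_matches_exhaustive_recomputation(seed):
    """<= 6 strains: topology and merge heights equal a naive UPGMA that
    re-averages all cluster pair distances at every step."""
    rng = np.random.default_rng(seed)
    n = 6
    x = rng.random((n, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    tree = upgma(d, labels)
    got = tree_clades_with_heights(tree)
    expected = brute_force_upgma(d, labels)
    assert set(got) == set(expected)
    for clade, height in expected.items():
        assert got[clade] == pytest.approx(height, abs=1e-9)


def test_merge_heights_are_non_decreasing(panel):
    ibs = ibs_matrix(panel.restrict_to_covered().genotypes)
    tree = upgma(ibs.distances, ibs.strains)
    heights = tree_clades_with_heights(tree)
    for node, h in heights.items():
        for other, h2 in heights.items():
            if node < other:
                assert h <= h2 + 1e-12


def test_mds_reconstructs_a_right_triangle():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    emb = classical_mds(d, ["a", "b", "c"], k=2)
    coords = emb.coordinates.to_numpy()
    rebuilt = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    np.testing.assert_allclose(rebuilt, d, atol=1e-10)
    assert np.all(emb.eigenvalues[:2] > 0)


def test_mds_equilateral_distances_stay_equal():
    d = np.full((3, 3), 1.0)
    np.fill_diagonal(d, 0.0)
    emb = classical_mds(d, list("abc"), k=2)
    coords = emb.coordinates.to_numpy()
    rebuilt = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    off = rebuilt[np.triu_indices(3, 1)]
    np.testing.assert_allclose(off, off[0], atol=1e-10)


def test_mds_duplicated_strain_gets_identical_coordinates():
    d = np.array(
        [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
    )
    emb = classical_mds(d, ["twin1", "twin2", "other"], k=2)
    c = emb.coordinates
    # the second axis is degenerate (zero eigenvalue), so only agreement up
    # to numerical noise is meaningful there
    np.testing.assert_allclose(
        c.loc["twin1"].to_numpy(), c.loc["twin2"].to_numpy(), atol=1e-6
    )


def test_mds_k_beyond_n_minus_one_is_an_error():
    d = np.zeros((3, 3))
    with pytest.raises(ValueError):
        classical_mds(d, list("abc"), k=3)


def test_mds_agrees_with_independent_pcoa(panel):
    """Cross-check against scikit-bio's principal-coordinates analysis."""
    ibs = ibs_matrix(panel.restrict_to_covered().genotypes)
    emb = classical_mds(ibs.distances, ibs.strains, k=2)
    ref = pcoa(DistanceMatrix(ibs.distances, ids=ibs.strains),
               number_of_dimensions=2)
    ours = emb.coordinates.to_numpy()
    theirs = ref.samples.to_numpy()
    for axis in range(2):
        dot = np.dot(ours[:, axis], theirs[:, axis])
        sign = 1.0 if dot >= 0 else -1.0
        np.testing.assert_allclose(
            ours[:, axis], sign * theirs[:, axis], atol=1e-6
        )
    n_ref = len(ref.eigvals)
    np.testing.assert_allclose(
        np.sort(emb.eigenvalues)[::-1][:n_ref],
        np.sort(ref.eigvals.to_numpy())[::-1],
        atol=1e-8,
    )


def test_sister_strain_is_nearest_neighbor_and_dendrogram_sibling(panel):
    ibs = ibs_matrix(panel.restrict_to_covered().genotypes)
    assert ibs.nearest_neighbor(FOCAL_STRAIN) == SISTER_STRAIN
    tree = upgma(ibs.distances, ibs.strains)
    focal_tip = tree.find(FOCAL_STRAIN)
    siblings = {
        t.name for t in focal_tip.parent.children if t.name != FOCAL_STRAIN
    }
    assert siblings == {SISTER_STRAIN}
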