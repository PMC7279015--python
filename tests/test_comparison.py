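"""Panel comparison: carrier profiling, partition logic, subset counts,
most-common selection, and truth-table recovery on synthetic data."""

import pandas as pd
import pytest

from strainsnp.comparison import (
    CATEGORY_FOCAL,
    CATEGORY_HYPERTENSIVE,
    CATEGORY_NORMOTENSIVE,
    CATEGORY_OTHER,
    LABEL_CONTROL,
    LABEL_EXCLUSIVE,
    LABEL_HYPERTENSIVE,
    StrainPanel,
    combination_counts,
    partition_counts,
    profile_variant,
    profile_variants,
    select_most_common,
)
from strainsnp.reporting import load_most_common_table, strain_list
from strainsnp.simulate import (
    FOCAL_STRAIN,
    HYPERTENSIVE_STRAINS,
    NORMOTENSIVE_STRAINS,
    OTHER_CONTROL_STRAINS,
)
from strainsnp.variants import Variant


def small_panel(rows, categories, coverage=None):
    """rows: {(chrom,pos): (ref, {strain: allele})}."""
    strains = sorted(categories)
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["chrom", "pos"])
    genotypes = pd.DataFrame(
        {
            s: [rows[k][1].get(s, rows[k][0]) for k in sorted(rows)]
            for s in strains
        },
        index=index,
        dtype=object,
    )
    refs = pd.Series([rows[k][0] for k in sorted(rows)], index=index)
    cov = (
        pd.Series([coverage[k] for k in sorted(rows)], index=index)
        if coverage
        else None
    )
    return StrainPanel(genotypes, refs, categories, cov)


CATS = {
    "H1": CATEGORY_HYPERTENSIVE,
    "H2": CATEGORY_HYPERTENSIVE,
    "N1": CATEGORY_NORMOTENSIVE,
    "O1": CATEGORY_OTHER,
}


def test_absent_locus_is_focal_exclusive():
    panel = small_panel({("chr1", 10): ("A", {})}, CATS)
    prof = profile_variant(Variant("chr1", 99, "A", "G"), panel)
    assert prof.carriers == frozenset()
    assert prof.partition_label == LABEL_EXCLUSIVE
    assert prof.n_hypertensive_carriers == 1  # the focal strain itself


def test_ref_mismatch_is_a_coordinate_fault():
    panel = small_panel({("chr1", 10): ("A", {})}, CATS)
    with pytest.raises(ValueError, match="reference allele mismatch"):
        profile_variant(Variant("chr1", 10, "C", "G"), panel)


def test_control_sharing_dominates_hypertensive_sharing():
    panel = small_panel(
        {("chr1", 10): ("A", {"H1": "G", "N1": "G"})}, CATS
    )
    prof = profile_variant(Variant("chr1", 10, "A", "G"), panel)
    assert prof.partition_label == LABEL_CONTROL
    assert prof.carriers == frozenset({"H1", "N1"})


def test_missing_genotype_never_counts_as_carriage():
    panel = small_panel(
        {("chr1", 10): ("A", {"H1": "G", "N1": None})}, CATS
    )
    prof = profile_variant(Variant("chr1", 10, "A", "G"), panel)
    assert prof.partition_label == LABEL_HYPERTENSIVE


def test_restrict_to_covered_counts_match_mask():
    rows = {("chr1", p): ("A", {}) for p in range(1, 21)}
    coverage = {k: (k[1] % 3 == 0) for k in rows}
    panel = small_panel(rows, CATS, coverage)
    restricted = panel.restrict_to_covered()
    assert restricted.n_loci == sum(coverage.values())
    assert restricted.strains == panel.strains
    # all-true mask is the identity
    full = small_panel(rows, CATS)
    assert full.restrict_to_covered().n_loci == len(rows)


def test_partition_counts_are_exhaustive_disjoint_and_order_free():
    rows = {}
    for p in range(1, 11):  # 10 control-shared
        rows[("chr1", p)] = ("A", {"N1": "G"})
    for p in range(11, 16):  # 5 hypertensive-shared
        rows[("chr1", p)] = ("A", {"H1": "G"})
    for p in range(16, 18):  # 2 exclusive
        rows[("chr1", p)] = ("A", {})
    panel = small_panel(rows, CATS)
    variants = [Variant("chr1", p, "A", "G") for p in range(1, 18)]
    profiles = profile_variants(variants, panel)
    assert partition_counts(profiles) == (10, 5, 2)
    assert partition_counts(reversed(profiles)) == (10, 5, 2)
    assert sum(partition_counts(profiles)) == len(profiles)


def test_combination_counts_enumerate_exact_subsets():
    rows = {
        ("chr1", 1): ("A", {"H1": "G"}),
        ("chr1", 2): ("A", {"H1": "G", "H2": "G"}),
        ("chr1", 3): ("A", {"H1": "G", "H2": "G"}),
    }
    panel = small_panel(rows, CATS)
    profiles = profile_variants(
        [Variant("chr1", p, "A", "G") for p in (1, 2, 3)], panel
    )
    combos = combination_counts(profiles, panel, include_focal=False)
    assert combos == {
        frozenset({"H1"}): 1,
        frozenset({"H1", "H2"}): 2,
    }
    assert sum(combos.values()) == partition_counts(profiles)[1]


def test_select_most_common_is_monotone_in_min_strains():
    rows = {
        ("chr1", 1): ("A", {"H1": "G", "H2": "G"}),
        ("chr1", 2): ("A", {"H1": "G"}),
        ("chr1", 3): ("A", {}),
    }
    panel = small_panel(rows, CATS)
    profiles = profile_variants(
        [Variant("chr1", p, "A", "G") for p in (1, 2, 3)], panel
    )
    sizes = [len(select_most_common(profiles, m)) for m in (1, 2, 3, 4)]
    assert sizes == sorted(sizes, reverse=True)
    # min_strains=1 returns every hypertensive-shared profile
    assert len(select_most_common(profiles, 1)) == partition_counts(profiles)[1]
    # a threshold beyond the panel yields nothing
    assert select_most_common(profiles, 99) == []


# ---------------------------------------------------------------------------
# worked-example fixture panel
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fixture_panel_and_profiles():
    table = load_most_common_table()
    categories = {FOCAL_STRAIN: CATEGORY_FOCAL}
    categories.update({s: CATEGORY_HYPERTENSIVE for s in HYPERTENSIVE_STRAINS})
    categories.update({s: CATEGORY_NORMOTENSIVE for s in NORMOTENSIVE_STRAINS})
    categories.update({s: CATEGORY_OTHER for s in OTHER_CONTROL_STRAINS})
    rows = {}
    for r in table.itertuples():
        key = (str(r.chrom), int(r.pos))
        carriers = {
            s: "G" for s in strain_list(r.strains) if s != FOCAL_STRAIN
        }
        rows.setdefault(key, ("A", {}))[1].update(carriers)
    panel = small_panel(rows, categories)
    variants = [Variant(c, p, "A", "G") for c, p in sorted(rows)]
    return panel, profile_variants(variants, panel)


def test_fixture_rs13449838_shared_by_eight_of_thirteen(
    fixture_panel_and_profiles,
):
    panel, profiles = fixture_panel_and_profiles
    prof = profile_variant(Variant("18", 59942888, "A", "G"), panel)
    expected = {
        "SHR/OlaIpcv", "SHRSP/Gla", "SHR/NCrlPrin", "SHR/NHsd",
        "SHR/OlaIpcvPrin", "SBH/Ygl", "ISIAH/Icgn",
    }
    assert prof.carriers == frozenset(expected)
    assert prof.n_hypertensive_carriers == 8


def test_fixture_no_variant_is_shared_by_all_thirteen(
    fixture_panel_and_profiles,
):
    panel, profiles = fixture_panel_and_profiles
    combos = combination_counts(profiles, panel)
    all13 = frozenset(HYPERTENSIVE_STRAINS) | {FOCAL_STRAIN}
    assert all13 not in combos
    assert max(len(k) for k in combos) == 8


def test_synthetic_partition_labels_match_planted_design(
    panel, truth, filtered_union
):
    covered = panel.restrict_to_covered()
    for fv in filtered_union:
        prof = profile_variant(fv.variant, covered)
        assert prof.partition_label == truth.expected_partition(fv.variant)
        assert prof.carriers | {FOCAL_STRAIN} == truth.strain_subset(fv.variant)


def test_synthetic_most_common_recovers_planted_blocks(
    scenario, panel, truth, filtered_union
):
    covered = panel.restrict_to_covered()
    profiles = profile_variants([fv.variant for fv in filtered_union], covered)
    selected = {p.variant.key for p in select_most_common(profiles, 6)}
    expected = set()
    for row in truth.frame[truth.frame.fate == "pass"].itertuples():
        subset = set(row.strains.split(";"))
        n_hyp = len(subset & (set(HYPERTENSIVE_STRAINS) | {FOCAL_STRAIN}))
        if (
            truth.expected_partition(
                Variant(row.chrom, int(row.pos), row.ref, row.alt)
            )
            == LABEL_HYPERTENSIVE
            and n_hyp >= 6
        ):
            expected.add((row.chrom, int(row.pos), row.alt))
    assert selected == expected
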