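"""Screening tools: planted-truth recovery, brute-force parity, dualities."""

import numpy as np
import pandas as pd
import pytest

from cartarget import (
    CohortMap,
    CohortSpec,
    GeneSet,
    build_cohort,
    fc_table,
    fold_change,
    log2_fold_change,
    median_profile,
    mwu_test,
    adjust_pvalues,
    screen_taa,
    simulate_cohort,
    skcm_compare,
    tissue_expression,
)
from cartarget.errors import CartargetError
from conftest import PLANTED_GENES


def test_screen_finds_exactly_the_planted_genes(small_cohort, small_sim):
    res = screen_taa(small_cohort, small_sim.gene_set, fc_threshold=15, direction="over")
    assert sorted(res.table["gene"]) == sorted(PLANTED_GENES)
    assert res.universe_size == 200  # BH ran over every tested gene
    assert (res.table["adj_p"] < 0.05).all()
    assert (res.table["fc"] >= 15).all()
    # frozen sort order: |log2fc| descending
    assert (res.table["log2fc"].abs().diff().dropna() <= 1e-12).all()


def test_screen_null_cohort_reports_nothing(null_sim):
    cohort = build_cohort("COAD", null_sim.tcga, null_sim.gtex,
                          null_sim.annotations, null_sim.cohort_map)
    res = screen_taa(cohort, null_sim.gene_set, fc_threshold=15, direction="over")
    assert res.table.empty
    assert res.universe_size == 200


def test_screen_matches_per_gene_bruteforce(small_cohort):
    """Vectorized screen row-for-row equals direct stats calls per gene."""
    res = screen_taa(small_cohort, None, fc_threshold=2, direction="over")
    genes = list(res.universe["gene"])[:100]
    sub = res.universe.set_index("gene").loc[genes]
    pvals = []
    for g in genes:
        t = small_cohort.class_values(g, "primary_tumor")
        c = small_cohort.class_values(g, "control")
        assert sub.loc[g, "fc"] == pytest.approx(fold_change(t, c), rel=1e-12)
        assert sub.loc[g, "log2fc"] == pytest.approx(log2_fold_change(t, c), rel=1e-12)
        assert sub.loc[g, "p_value"] == pytest.approx(mwu_test(t, c), rel=1e-9)
        pvals.append(mwu_test(t, c))


def test_screen_adjusts_over_the_full_universe(small_cohort, small_sim):
    """Dropping null genes from the universe changes the planted genes' adj_p."""
    full = screen_taa(small_cohort, small_sim.gene_set, 15, "over")
    tiny_universe = GeneSet("tiny", set(PLANTED_GENES) | {"G00002", "G00003"})
    small = screen_taa(small_cohort, tiny_universe, 15, "over")
    assert small.universe_size == 5
    g = PLANTED_GENES[0]
    adj_full = full.universe.set_index("gene").loc[g, "adj_p"]
    adj_small = small.universe.set_index("gene").loc[g, "adj_p"]
    assert adj_full != adj_small


def test_screen_direction_duality(small_sim):
    """'under' on the swapped cohort mirrors 'over', FC reciprocal."""
    cohort = build_cohort("COAD", small_sim.tcga, small_sim.gtex,
                          small_sim.annotations, small_sim.cohort_map)
    over = screen_taa(cohort, small_sim.gene_set, 15, "over")
    swapped = type(cohort)(
        tumor_code=cohort.tumor_code,
        matrix=cohort.matrix,
        primary_ids=cohort.control_ids,
        metastatic_ids=[],
        control_ids=cohort.primary_ids,
        control_tissue={},
    )
    under = screen_taa(swapped, small_sim.gene_set, 15, "under")
    assert sorted(over.table["gene"]) == sorted(under.table["gene"])
    o = over.universe.set_index("gene")
    u = under.universe.set_index("gene")
    np.testing.assert_allclose(o["fc"], 1.0 / u["fc"], rtol=1e-9)
    np.testing.assert_allclose(o["log2fc"], -u["log2fc"], rtol=1e-9)
    np.testing.assert_allclose(o["p_value"], u["p_value"], rtol=1e-9)


def test_screen_parameter_validation(small_cohort):
    with pytest.raises(CartargetError):
        screen_taa(small_cohort, None, fc_threshold=1.0)
    with pytest.raises(CartargetError):
        screen_taa(small_cohort, None, 2.0, "sideways")
    with pytest.raises(CartargetError):
        screen_taa(small_cohort, GeneSet("alien", {"NOPE"}), 2.0, "over")


# --- fc_table ---------------------------------------------------------------

def test_fc_table_single_cell_equals_direct_call(small_sim, small_cohort):
    g = PLANTED_GENES[0]
    table = fc_table([g], ["COAD"], "fc", small_sim.tcga, small_sim.gtex,
                     small_sim.annotations, small_sim.cohort_map)
    direct = fold_change(small_cohort.class_values(g, "primary_tumor"),
                         small_cohort.class_values(g, "control"))
    assert table.loc[g, "COAD"] == pytest.approx(direct, rel=1e-12)
    assert table.shape == (1, 1)


def test_fc_table_planted_gene_high_only_in_its_cohort(small_sim):
    table = fc_table(PLANTED_GENES + ["G00002"], ["COAD"], "fc",
                     small_sim.tcga, small_sim.gtex, small_sim.annotations,
                     small_sim.cohort_map)
    assert (table.loc[PLANTED_GENES, "COAD"] > 10).all()
    assert table.loc["G00002", "COAD"] == pytest.approx(1.0, abs=0.5)


def test_fc_table_log2fc_is_median_difference_not_log_of_ratio():
    """On skewed groups, median-difference log2FC != log2(median ratio)."""
    t, c = [0, 0, 100], [1, 1, 1]
    assert log2_fold_change(t, c) == pytest.approx(-1.0)  # median log2(T+1)=0, C=1
    assert np.log2(fold_change(t, c)) == pytest.approx(np.log2(0.01 / 1.01))
    assert log2_fold_change(t, c) != pytest.approx(np.log2(fold_change(t, c)))


def test_fc_table_unknown_inputs_listed(small_sim):
    with pytest.raises(CartargetError, match="NOPE"):
        fc_table(["NOPE"], ["COAD"], "fc", small_sim.tcga, small_sim.gtex,
                 small_sim.annotations, small_sim.cohort_map)
    with pytest.raises(CartargetError, match="XXXX"):
        fc_table([PLANTED_GENES[0]], ["XXXX"], "fc", small_sim.tcga,
                 small_sim.gtex, small_sim.annotations, small_sim.cohort_map)


# --- median_profile ---------------------------------------------------------

def test_median_profile_omits_empty_metastatic_class(small_sim):
    df = median_profile(PLANTED_GENES[0], small_sim.tcga, small_sim.gtex,
                        small_sim.annotations, small_sim.cohort_map, ["COAD"])
    assert list(df["group"]) == ["primary_tumor", "control"]  # no metastatic row
    assert list(df["n"]) == [40, 40]


def test_median_profile_includes_metastatic_when_present():
    spec = CohortSpec(seed=5, tumor_code="SKCM", n_genes=20, n_primary=10,
                      n_metastatic=6, n_adjacent_normal=4,
                      tissues={"Skin": 8})
    sim = simulate_cohort(spec)
    df = median_profile("G00000", sim.tcga, sim.gtex, sim.annotations,
                        sim.cohort_map, ["SKCM"])
    assert list(df["group"]) == ["primary_tumor", "metastatic", "control"]
    assert list(df["n"]) == [10, 6, 12]


def test_median_profile_constant_matrix_reports_that_constant(small_sim):
    sim = simulate_cohort(CohortSpec(seed=1, n_genes=5, sigma=0.0,
                                     baseline_range=(3.0, 3.0)))
    df = median_profile("G00000", sim.tcga, sim.gtex, sim.annotations,
                        sim.cohort_map, ["COAD"])
    # 2^3 - 1 = 7 TPM everywhere
    assert df["median_tpm"].tolist() == pytest.approx([7.0, 7.0])


# --- tissue_expression ------------------------------------------------------

def _tissue_sim():
    spec = CohortSpec(
        seed=11, n_genes=50, n_primary=30, n_adjacent_normal=5,
        tissues={"Colon": 20, "Kidney": 20, "Lung": 20},
        planted=[("G00007", "primary_tumor", 32.0),
                 ("G00007", "tissue:Kidney", 32.0)],
    )
    return simulate_cohort(spec)


def test_tissue_expression_without_tumor_is_descriptive(small_sim):
    df = tissue_expression("G00000", small_sim.gtex, small_sim.annotations)
    assert list(df.columns) == ["group", "n", "median_tpm", "median_log2"]
    assert set(df["group"]) == {"Colon"}


def test_tissue_expression_flags_offtumor_tissue():
    sim = _tissue_sim()
    cohort = build_cohort("COAD", sim.tcga, sim.gtex, sim.annotations,
                          sim.cohort_map)
    df = tissue_expression("G00007", sim.gtex, sim.annotations, cohort)
    by = df.set_index("group")
    # tumor is ~32x Colon and Lung (log2fc ~ 5), matches Kidney (~0)
    assert by.loc["Colon", "log2fc"] == pytest.approx(5.0, abs=0.6)
    assert by.loc["Lung", "log2fc"] == pytest.approx(5.0, abs=0.6)
    assert bool(by.loc["Colon", "significant"])
    assert by.loc["Kidney", "log2fc"] == pytest.approx(0.0, abs=0.4)
    assert not bool(by.loc["Kidney", "significant"])
    # leading row summarizes the tumor group
    assert df.iloc[0]["group"] == "COAD primary tumor"


# --- skcm_compare -----------------------------------------------------------

def _three_group_cohort(met_fc):
    spec = CohortSpec(seed=21, tumor_code="SKCM", n_genes=10, n_primary=25,
                      n_metastatic=25, n_adjacent_normal=5,
                      tissues={"Skin": 20},
                      planted=[("G00003", "metastatic", met_fc)])
    sim = simulate_cohort(spec)
    return build_cohort("SKCM", sim.tcga, sim.gtex, sim.annotations,
                        sim.cohort_map)


def test_skcm_compare_null_gene_no_significant_pairs():
    cohort = _three_group_cohort(8.0)
    res = skcm_compare("G00001", cohort)  # not planted
    assert not res.pairwise["significant"].any()
    assert res.summaries["n"].tolist() == [25, 25, 25]


def test_skcm_compare_metastatic_shift_gives_two_significant_pairs():
    cohort = _three_group_cohort(8.0)
    res = skcm_compare("G00003", cohort)
    sig = res.pairwise.set_index(["group_a", "group_b"])["significant"]
    assert bool(sig[("metastatic", "primary_tumor")])
    assert bool(sig[("metastatic", "control")])
    assert not bool(sig[("primary_tumor", "control")])


def test_skcm_compare_requires_all_three_classes(small_cohort):
    with pytest.raises(CartargetError, match="metastatic"):
        skcm_compare("G00000", small_cohort)
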