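"""Split-attribute ranking, core selection, low-cost augmentation and
paired subset comparison."""

import numpy as np
import pytest

from pollentree import (
    BEST6,
    EASIEST4,
    augment_low_cost,
    collect_split_attributes,
    compare_subsets,
    default_schema,
    run_full_procedure,
    select_core,
)


@pytest.fixture(scope="module")
def schema():
    return default_schema()


def test_ranking_counts_trees_not_nodes(schema):
    sets = [{"max_axis", "n_pores"}, {"max_axis", "wall"},
            {"max_axis", "n_pores"}]
    ranking = collect_split_attributes(sets, schema)
    assert ranking == (("max_axis", 3), ("n_pores", 2), ("wall", 1))


def test_ranking_ties_break_by_schema_order(schema):
    ranking = collect_split_attributes([{"wall", "min_axis"}], schema)
    assert [a for a, _ in ranking] == ["min_axis", "wall"]


def test_ranking_of_leaf_only_trees_is_empty(schema):
    assert collect_split_attributes([set(), set()], schema) == ()


def test_select_core_union_and_min_frequency():
    ranking = (("a", 3), ("b", 2), ("c", 1))
    assert select_core(ranking) == ("a", "b", "c")
    assert select_core(ranking, min_count=2) == ("a", "b")
    assert select_core((), min_count=1) == ()


def test_augment_best6_adds_exactly_the_low_cost_three(schema):
    augmented = augment_low_cost(BEST6, schema)
    assert set(augmented) == set(BEST6) | {
        "n_top_pores", "n_oblique_pores", "min_oncus_width"}
    assert len(augmented) == 9


def test_augment_is_idempotent_and_monotonic(schema):
    once = augment_low_cost(BEST6, schema)
    twice = augment_low_cost(once, schema)
    assert set(once) == set(twice)
    assert set(BEST6) <= set(once)
    assert augment_low_cost((), schema) == ()


def test_augment_rejects_unknown_attribute(schema):
    with pytest.raises(KeyError):
        augment_low_cost(("bogus",), schema)


def test_identical_subsets_have_zero_difference(default_table):
    results = compare_subsets(
        default_table,
        {"one": list(BEST6), "two": list(BEST6)},
        k=5, repeats=3, seed=4,
    )
    assert results["one"].mean_percent_correct == pytest.approx(
        results["two"].mean_percent_correct, abs=1e-12)


def test_compare_uses_shared_fold_assignments(default_table):
    # with paired folds, per-repetition accuracies of the same subset
    # requested under two names must match repetition by repetition
    results = compare_subsets(
        default_table,
        {"x": list(EASIEST4), "y": list(EASIEST4)},
        k=5, repeats=4, seed=1,
    )
    assert np.array_equal(results["x"].repetition_means,
                          results["y"].repetition_means)


def test_full_subset_beats_single_constant_attribute(separable_table):
    results = compare_subsets(
        separable_table,
        {"all": ["x", "z"], "constant": ["z"]},
        k=5, repeats=2, seed=0,
    )
    diff = (results["all"].mean_percent_correct
            - results["constant"].mean_percent_correct)
    assert diff > 0


def test_full_procedure_report_structure(default_table):
    report = run_full_procedure(default_table, k=5, repeats=2, seed=7)
    assert set(report.subsets) == {"full", "core", "augmented", "easiest"}
    assert set(report.core) <= {a for a, _ in report.ranking}
    assert set(report.core) <= set(report.augmented)
    assert report.subsets["easiest"] == EASIEST4
    d = report.to_dict()
    assert set(d["subset_mean_percent_correct"]) == set(report.subsets)
    assert len(d["pairwise_differences_pp"]) == 12  # 4 subsets, ordered pairs
    assert d["pairwise_differences_pp"]["core-easiest"] == pytest.approx(
        report.subset_means["core"] - report.subset_means["easiest"])
    assert 0 < d["resubstitution_percent"] <= 100


def test_full_procedure_deterministic_per_seed(default_table):
    r1 = run_full_procedure(default_table, k=5, repeats=2, seed=3)
    r2 = run_full_procedure(default_table, k=5, repeats=2, seed=3)
    assert r1.to_dict() == r2.to_dict()
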