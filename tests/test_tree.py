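"""Gain-ratio induction: closed forms, missing-value semantics, oracle
agreement, classification routing and rule export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollentree import (
    AttributeSpec,
    FeatureTable,
    InductionParams,
    Schema,
    SplitTest,
    best_split_for_attribute,
    build_tree,
    class_entropy,
    classify,
    evaluate,
    evaluate_split,
    export_rules,
    parse_rules,
    split_attributes,
    tree_shape,
)
from conftest import make_xy_table
from oracles import brute_force_best_split, random_numeric_table


# ---------------------------------------------------------------------------
# entropy

@pytest.mark.parametrize("counts, expected", [
    ((5, 0, 0), 0.0),
    ((2, 2), 1.0),
    ((1, 3), 0.8112781244591328),  # -(1/4 log2 1/4 + 3/4 log2 3/4)
    ((1, 1, 1, 1), 2.0),
])
def test_class_entropy_closed_forms(counts, expected):
    assert class_entropy(counts) == pytest.approx(expected, abs=1e-9)


def test_class_entropy_rejects_zero_total():
    with pytest.raises(ValueError):
        class_entropy([0.0, 0.0])


# ---------------------------------------------------------------------------
# split evaluation

def test_evaluate_split_symmetric_two_class(two_class_schema):
    table = make_xy_table(two_class_schema, [1, 1, 2, 2], "aabb")
    ev = evaluate_split(table, SplitTest("x", threshold=1.0))
    assert ev.known_fraction == 1.0
    assert ev.gain == pytest.approx(1.0, abs=1e-9)
    assert ev.split_info == pytest.approx(1.0, abs=1e-9)
    assert ev.gain_ratio == pytest.approx(1.0, abs=1e-9)


def test_evaluate_split_single_branch_has_zero_gain(two_class_schema):
    table = make_xy_table(two_class_schema, [1, 1, 2, 2], "aabb")
    ev = evaluate_split(table, SplitTest("x", threshold=10.0))
    assert ev.gain == 0.0
    assert ev.gain_ratio is None
    assert not ev.admissible


def test_evaluate_split_scales_gain_by_known_fraction(two_class_schema):
    # one of the four records lacks the attribute: F = 3/4, and the
    # known-subset gain is the full entropy of its class counts (2a, 1b)
    table = make_xy_table(two_class_schema, [1, 1, 2, None], "aabb")
    ev = evaluate_split(table, SplitTest("x", threshold=1.0))
    assert ev.known_fraction == pytest.approx(0.75)
    assert ev.gain == pytest.approx(0.75 * class_entropy([2, 1]), abs=1e-9)
    # split information counts the missing group as its own branch
    assert ev.split_info == pytest.approx(
        class_entropy([2, 1, 1]), abs=1e-9)


def test_best_split_reports_observed_value_threshold(two_class_schema):
    table = make_xy_table(two_class_schema, [1, 2, 3, 4], "aabb")
    ev = best_split_for_attribute(table, "x")
    assert ev.test.threshold == 2.0
    assert ev.gain_ratio == pytest.approx(1.0, abs=1e-9)


def test_best_split_constant_attribute_is_none(two_class_schema):
    table = make_xy_table(two_class_schema, [3, 3, 3, 3], "aabb")
    assert best_split_for_attribute(table, "x") is None


def test_best_split_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    params = InductionParams(prune=False)
    checked = 0
    for _ in range(60):
        table = random_numeric_table(rng)
        expected = brute_force_best_split(table, params)
        tree = build_tree(table, params=params)
        if expected is None:
            assert tree.root.is_leaf
            continue
        assert not tree.root.is_leaf
        got = (tree.root.test.attribute, tree.root.test.threshold)
        assert got == expected
        checked += 1
    assert checked > 20


# ---------------------------------------------------------------------------
# induction

def test_single_class_table_yields_single_leaf(two_class_schema):
    table = make_xy_table(two_class_schema, [1, 2, 3, 4], "aaaa")
    tree = build_tree(table)
    assert tree.root.is_leaf
    assert tree.class_labels[tree.root.label_idx] == "a"


def test_perfect_separator_is_chosen_over_constant(separable_table):
    tree = build_tree(separable_table)
    assert tree.root.test.attribute == "x"
    assert split_attributes(tree) == {"x"}
    assert evaluate(tree, separable_table).percent_correct == 100.0


def test_pore_count_style_root_split():
    # one taxon has counts {4,5,6}, the others {2,3}; a noisy size
    # attribute cannot compete with the clean count threshold at 3
    rng = np.random.default_rng(5)
    schema = Schema(
        (AttributeSpec("n_pores", "count"), AttributeSpec("size", "continuous")),
        class_name="cls", class_labels=("A", "B", "C"),
    )
    n = 20
    df = pd.DataFrame({
        "n_pores": list(rng.integers(4, 7, n).astype(float))
        + list(rng.integers(2, 4, 2 * n).astype(float)),
        "size": rng.normal(20, 3, 3 * n),
        "cls": ["A"] * n + ["B"] * n + ["C"] * n,
    })
    tree = build_tree(FeatureTable(schema, df))
    assert tree.root.test.attribute == "n_pores"
    assert tree.root.test.threshold == 3.0


def test_fractional_weights_conserved_at_every_node(default_table):
    tree = build_tree(default_table, params=InductionParams(prune=False))

    def check(node):
        if node.is_leaf:
            return
        child_total = sum(c.weight for c in node.children)
        assert child_total == pytest.approx(node.weight, rel=1e-9)
        for c in node.children:
            check(c)

    check(tree.root)


def test_identical_input_gives_identical_tree(default_table):
    t1 = build_tree(default_table)
    t2 = build_tree(default_table)
    assert tree_shape(t1) == tree_shape(t2)
    assert export_rules(t1) == export_rules(t2)


def test_unpruned_training_accuracy_is_100_on_separable(separable_table):
    tree = build_tree(separable_table, params=InductionParams(prune=False))
    assert evaluate(tree, separable_table).percent_correct == 100.0


def test_build_tree_rejects_empty_inputs(two_class_schema, default_table):
    empty = make_xy_table(two_class_schema, [], "")
    with pytest.raises(ValueError):
        build_tree(empty)
    with pytest.raises(ValueError):
        build_tree(default_table, attrs=[])
    with pytest.raises(ValueError):
        build_tree(default_table, attrs=["no_such_attribute"])


# ---------------------------------------------------------------------------
# classification

def test_missing_root_value_routes_fractionally(two_class_schema):
    # 3 records go left (class a), 1 right (class b): branch
    # proportions 0.75 / 0.25
    table = make_xy_table(two_class_schema, [1, 1, 1, 5], "aaab")
    tree = build_tree(table, params=InductionParams(min_leaf_weight=1,
                                                    prune=False))
    dist, pred = classify(tree, {"x": None})
    assert dist == pytest.approx({"a": 0.75, "b": 0.25})
    assert pred == "a"


def test_known_value_follows_single_path(two_class_schema):
    table = make_xy_table(two_class_schema, [1, 1, 1, 5], "aaab")
    tree = build_tree(table, params=InductionParams(min_leaf_weight=1,
                                                    prune=False))
    dist, pred = classify(tree, {"x": 5.0})
    assert pred == "b"
    assert dist["b"] == pytest.approx(1.0)


def test_majority_leaf_accuracy_matches_class_share(two_class_schema):
    table = make_xy_table(two_class_schema, [1.0] * 10, "a" * 6 + "b" * 4)
    tree = build_tree(table)
    assert tree.root.is_leaf
    res = evaluate(tree, table)
    assert res.percent_correct == pytest.approx(60.0)
    assert res.confusion.to_numpy().sum() == pytest.approx(10.0)


def test_confusion_matrix_conserves_weight(default_table):
    tree = build_tree(default_table)
    res = evaluate(tree, default_table)
    assert res.confusion.to_numpy().sum() == pytest.approx(
        default_table.total_weight())


# ---------------------------------------------------------------------------
# rule text

def test_rules_round_trip_to_identical_shape(default_table):
    tree = build_tree(default_table)
    text = export_rules(tree)
    assert parse_rules(text) == tree_shape(tree)
    # every internal line shows attribute and 2-decimal threshold
    for line in text.splitlines():
        if line.strip().startswith("class:"):
            assert "(" in line and "/" in line
        else:
            assert any(op in line for op in ("<=", ">", "="))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rules_round_trip_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    table = random_numeric_table(rng, max_records=16, max_attrs=3)
    tree = build_tree(table, params=InductionParams(prune=False))
    assert parse_rules(export_rules(tree)) == tree_shape(tree)


def test_split_attributes_of_leaf_tree_is_empty(two_class_schema):
    table = make_xy_table(two_class_schema, [1.0] * 4, "aaaa")
    assert split_attributes(build_tree(table)) == set()
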