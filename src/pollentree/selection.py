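"""Split-attribute feature selection and subset comparison.

The selection procedure: build a tree on the full dataset, run one
stratified k-fold CV recording the split attributes of every fold tree,
rank attributes by the number of trees using them, take the union (or a
minimum-frequency subset) as the core discriminative set, augment it
with features obtainable at low extra cost (derivation inputs and
same-measurement-group attributes — e.g. counting pores to obtain the
total already yields the top/lateral/oblique counts, and measuring all
onci for the maximum width yields the minimum too), and compare the
named subsets by repeated cross-validation on *identical* fold
assignments (a paired comparison).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .crossval import (
    CVRunResult,
    RepeatedCVResult,
    _run_cv_compiled,
    _spawn_seeds,
    stratified_folds,
)
from .schema import EASIEST4, Schema
from .table import FeatureTable
from .tree import (
    CompiledTable,
    DecisionTree,
    InductionParams,
    build_tree,
    evaluate,
    split_attributes,
)

__all__ = [
    "SelectionReport",
    "collect_split_attributes",
    "select_core",
    "augment_low_cost",
    "compare_subsets",
    "run_full_procedure",
]


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the full selection procedure."""

    ranking: tuple[tuple[str, int], ...]       # attribute -> #trees using it
    core: tuple[str, ...]
    augmented: tuple[str, ...]
    subsets: dict[str, tuple[str, ...]]        # all compared subsets
    subset_results: dict[str, RepeatedCVResult]
    resubstitution_percent: float              # full-data tree on itself
    full_tree: DecisionTree
    cv_run: CVRunResult

    @property
    def subset_means(self) -> dict[str, float]:
        return {name: r.mean_percent_correct
                for name, r in self.subset_results.items()}

    def pairwise_differences(self) -> dict[str, float]:
        """All ordered pairwise accuracy differences, percentage points."""
        means = self.subset_means
        return {
            f"{a}-{b}": means[a] - means[b]
            for a in means for b in means if a != b
        }

    def to_dict(self) -> dict:
        return {
            "ranking": [[a, int(c)] for a, c in self.ranking],
            "core": list(self.core),
            "augmented": list(self.augmented),
            "subsets": {k: list(v) for k, v in self.subsets.items()},
            "subset_mean_percent_correct": {
                k: float(v) for k, v in self.subset_means.items()
            },
            "pairwise_differences_pp": {
                k: float(v) for k, v in self.pairwise_differences().items()
            },
            "resubstitution_percent": float(self.resubstitution_percent),
            "cv_mean_percent_correct": float(self.cv_run.mean_percent_correct),
        }


def collect_split_attributes(
    trees_or_sets,
    schema: Schema,
) -> tuple[tuple[str, int], ...]:
    """Rank attributes by the number of trees whose internal nodes use
    them; descending count, ties broken by schema order."""
    counts: Counter[str] = Counter()
    for t in trees_or_sets:
        attrs = split_attributes(t) if isinstance(t, DecisionTree) else set(t)
        counts.update(attrs)
    order = {name: i for i, name in enumerate(schema.names)}
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], order[kv[0]]))
    return tuple((a, int(c)) for a, c in ranked)


def select_core(
    ranking,
    min_count: int = 1,
) -> tuple[str, ...]:
    """Attributes appearing in at least ``min_count`` trees.

    The default (union rule, min_count=1) keeps every attribute that any
    tree split on; ranking order is preserved."""
    return tuple(a for a, c in ranking if c >= min_count)


def augment_low_cost(
    core,
    schema: Schema,
) -> tuple[str, ...]:
    """Close a subset under low-cost co-measured features.

    For every attribute in ``core`` add its derivation inputs and every
    attribute in the same measurement group, iterating to a fixed point
    (hence idempotent).  Result is in schema order."""
    for a in core:
        if a not in schema:
            raise KeyError(f"unknown attribute {a!r}")
    selected = set(core)
    while True:
        extra: set[str] = set()
        for name in selected:
            spec = schema[name]
            extra.update(spec.derived_from)
            if spec.measurement_group:
                extra.update(
                    a.name for a in schema.attributes
                    if a.measurement_group == spec.measurement_group
                )
        if extra <= selected:
            break
        selected |= extra
    return tuple(a for a in schema.names if a in selected)


def compare_subsets(
    table: FeatureTable,
    subsets: dict[str, list[str]],
    params: InductionParams | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, RepeatedCVResult]:
    """Repeated-CV accuracy per subset on identical fold assignments.

    Every repetition uses one fold assignment shared by all subsets
    (same spawned seed sequence), so subset differences are paired."""
    params = params or InductionParams()
    comp = CompiledTable(table)
    fold_seeds = _spawn_seeds(seed, repeats)
    per_subset: dict[str, list[CVRunResult]] = {n: [] for n in subsets}
    freqs: dict[str, Counter] = {n: Counter() for n in subsets}
    for s in fold_seeds:
        folds = stratified_folds(table, k, s)
        for name, attrs in subsets.items():
            run = _run_cv_compiled(comp, folds, list(attrs), params)
            per_subset[name].append(run)
            for attrset in run.fold_split_attributes:
                freqs[name].update(attrset)
    return {
        name: RepeatedCVResult(
            repetitions=repeats,
            runs=tuple(runs),
            attribute_frequencies=dict(freqs[name]),
        )
        for name, runs in per_subset.items()
    }


def run_full_procedure(
    table: FeatureTable,
    params: InductionParams | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    easiest: tuple[str, ...] = EASIEST4,
    min_count: int = 1,
) -> SelectionReport:
    """The whole pipeline: full-data tree, one CV with split-attribute
    recording, core selection, low-cost augmentation, and paired
    repeated-CV comparison of {full, core, augmented, easiest}."""
    params = params or InductionParams()
    schema = table.schema
    full_tree = build_tree(table, params=params)
    resub = evaluate(full_tree, table).percent_correct
    cv_seed, cmp_seed = _spawn_seeds(seed, 2)
    comp = CompiledTable(table)
    folds = stratified_folds(table, k, cv_seed)
    cv_run = _run_cv_compiled(comp, folds, None, params)
    ranking = collect_split_attributes(
        [split_attributes(full_tree), *cv_run.fold_split_attributes], schema
    )
    core = select_core(ranking, min_count=min_count)
    augmented = augment_low_cost(core, schema)
    subsets = {
        "full": list(schema.names),
        "core": list(core),
        "augmented": list(augmented),
        "easiest": list(easiest),
    }
    results = compare_subsets(table, subsets, params, k=k, repeats=repeats,
                              seed=cmp_seed)
    return SelectionReport(
        ranking=ranking,
        core=core,
        augmented=augmented,
        subsets={n: tuple(v) for n, v in subsets.items()},
        subset_results=results,
        resubstitution_percent=resub,
        full_tree=full_tree,
        cv_run=cv_run,
    )
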