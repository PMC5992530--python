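"""Stratified k-fold cross-validation, optionally repeated.

The study design: 225 grains (75 per taxon) assigned to five folds with
exactly equal per-taxon counts, so every tree is built on 180 records
(60 per taxon) and verified on 45 (15 per taxon); the whole procedure
is repeated with fresh random fold assignments to average out the
influence of the random selection.

Fold assignment shuffles records within each class with the seeded
generator and deals them round-robin, which guarantees per-class fold
counts differing by at most one (exactly equal when the class size is
divisible by k).  Fold-level accuracies are aggregated as their
unweighted mean; with equal-sized folds this equals pooled accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable
from .tree import (
    CompiledTable,
    DecisionTree,
    EvaluationResult,
    InductionParams,
    build_tree_compiled,
    evaluate_compiled,
    split_attributes,
)

__all__ = [
    "FoldAssignment",
    "CVRunResult",
    "RepeatedCVResult",
    "stratified_folds",
    "run_cv",
    "repeat_cv",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Per-record fold indices (a partition stratified by class)."""

    k: int
    fold_of: np.ndarray  # int per record, in [0, k)
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass(frozen=True)
class CVRunResult:
    """One k-fold pass: per-fold accuracy, confusion and split attributes."""

    k: int
    fold_accuracies: tuple[float, ...]
    fold_confusions: tuple[pd.DataFrame, ...]
    fold_split_attributes: tuple[frozenset[str], ...]

    @property
    def mean_percent_correct(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass(frozen=True)
class RepeatedCVResult:
    """R independent k-fold passes plus aggregates."""

    repetitions: int
    runs: tuple[CVRunResult, ...]
    attribute_frequencies: dict[str, int]  # trees (out of R*k) using attr

    @property
    def mean_percent_correct(self) -> float:
        return float(np.mean([r.mean_percent_correct for r in self.runs]))

    @property
    def repetition_means(self) -> np.ndarray:
        return np.array([r.mean_percent_correct for r in self.runs])


def stratified_folds(table: FeatureTable, k: int, seed: int) -> FoldAssignment:
    """Assign records to ``k`` folds with balanced class composition.

    Within each class, records are shuffled by the seeded generator and
    dealt round-robin to the folds; identical seeds yield identical
    assignments.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = table.classes.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fold_of = np.full(len(table), -1, dtype=int)
    for label in table.schema.class_labels:
        members = np.flatnonzero(classes == label)
        if len(members) == 0:
            continue
        if len(members) < k:
            raise ValueError(
                f"class {label!r} has {len(members)} records, fewer than "
                f"k={k}"
            )
        perm = rng.permutation(members)
        fold_of[perm] = np.arange(len(perm)) % k
    if (fold_of < 0).any():
        raise ValueError("record with class outside the schema labels")
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def _run_cv_compiled(
    comp: CompiledTable,
    folds: FoldAssignment,
    attrs: list[str] | None,
    params: InductionParams,
) -> CVRunResult:
    accs, confs, attr_sets = [], [], []
    for f in range(folds.k):
        tree = build_tree_compiled(comp, folds.train_indices(f), attrs,
                                   params)
        res: EvaluationResult = evaluate_compiled(tree, comp,
                                                  folds.test_indices(f))
        accs.append(res.percent_correct)
        confs.append(res.confusion)
        attr_sets.append(frozenset(split_attributes(tree)))
    return CVRunResult(
        k=folds.k,
        fold_accuracies=tuple(accs),
        fold_confusions=tuple(confs),
        fold_split_attributes=tuple(attr_sets),
    )


def run_cv(
    table: FeatureTable,
    attrs: list[str] | None = None,
    params: InductionParams | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVRunResult:
    """One stratified k-fold pass: build on k−1 folds, test on the held
    fold, recording accuracy and the split attributes of each fold tree."""
    params = params or InductionParams()
    folds = stratified_folds(table, k, seed)
    comp = CompiledTable(table)
    return _run_cv_compiled(comp, folds, attrs, params)


def repeat_cv(
    table: FeatureTable,
    attrs: list[str] | None = None,
    params: InductionParams | None = None,
    k: int = 5,
    repeats: int = 1000,
    seed: int = 0,
) -> RepeatedCVResult:
    """R independent repetitions of stratified k-fold CV.

    Fold assignments are drawn from seeds spawned deterministically
    from ``seed``; the overall mean is the mean of repetition means.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    params = params or InductionParams()
    comp = CompiledTable(table)
    fold_seeds = _spawn_seeds(seed, repeats)
    runs = []
    freq: Counter[str] = Counter()
    for s in fold_seeds:
        folds = stratified_folds(table, k, s)
        run = _run_cv_compiled(comp, folds, attrs, params)
        runs.append(run)
        for attrset in run.fold_split_attributes:
            freq.update(attrset)
    return RepeatedCVResult(
        repetitions=repeats,
        runs=tuple(runs),
        attribute_frequencies=dict(freq),
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> 1]
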