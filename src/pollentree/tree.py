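"""Gain-ratio (C4.5 / J4.8-style) decision-tree induction.

The split criterion is the gain ratio: information gain divided by the
split information (the entropy of the branch weight proportions).
Missing values are handled the C4.5 way:

* when evaluating a split on attribute ``a``, the information gain is
  computed on the subset with known ``a`` and multiplied by the known
  weight fraction ``F``; the split information includes the
  missing-weight group as an extra term;
* during induction and classification, a record whose split-attribute
  value is missing descends *all* branches with its weight multiplied
  by the branch proportions observed among known-valued records.

Numeric splits are binary at a threshold ``t`` (branches ``<= t`` and
``> t``); candidate thresholds are the midpoints of consecutive
distinct sorted values, and the chosen threshold is reported as the
largest observed value not exceeding the best midpoint, so thresholds
are always data values.  Nominal splits are multiway, one branch per
category.  Optional pessimistic pruning (subtree replacement using the
upper binomial confidence limit of the training error, confidence 0.25
by default) mirrors the J4.8 defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import Schema
from .table import FeatureTable

__all__ = [
    "InductionParams",
    "SplitTest",
    "SplitEvaluation",
    "TreeNode",
    "DecisionTree",
    "class_entropy",
    "evaluate_split",
    "best_split_for_attribute",
    "build_tree",
    "classify",
    "evaluate",
    "EvaluationResult",
    "export_rules",
    "parse_rules",
    "tree_shape",
    "split_attributes",
    "to_dot",
]

_GAIN_EPS = 1e-12
_TIE_EPS = 1e-10


# ---------------------------------------------------------------------------
# parameters and data compilation

@dataclass(frozen=True)
class InductionParams:
    """Induction settings (defaults mirror WEKA J4.8).

    min_leaf_weight
        Minimum total instance weight on each of at least two branches
        of an admissible split (J4.8 ``minNumObj``).
    prune
        Apply pessimistic subtree-replacement pruning.
    confidence
        Confidence factor of the pruning error estimate, in (0, 1).
    avg_gain_gate
        C4.5's admissibility heuristic restricting candidate numeric
        splits to those with at least average information gain
        (off by default; the criterion is plain gain-ratio maximisation).
    mdl_correction
        Subtract ``log2(number of candidate thresholds) / node weight``
        from the gain of numeric splits (the C4.5 release-8 penalty,
        on by default in J4.8); suppresses spurious razor-thin
        thresholds on uninformative attributes.
    """

    min_leaf_weight: float = 2.0
    prune: bool = True
    confidence: float = 0.25
    avg_gain_gate: bool = False
    mdl_correction: bool = True

    def __post_init__(self) -> None:
        if self.min_leaf_weight < 1:
            raise ValueError("min_leaf_weight must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")


class CompiledTable:
    """Numeric view of a FeatureTable for fast induction.

    Nominal attributes are coded as category indices; missing is NaN.
    """

    __slots__ = ("X", "y", "w", "schema", "attr_names", "is_nominal",
                 "n_cats", "class_labels")

    def __init__(self, table: FeatureTable) -> None:
        schema = table.schema
        self.schema = schema
        self.attr_names = list(schema.names)
        self.class_labels = list(schema.class_labels)
        n, p = len(table), len(self.attr_names)
        X = np.empty((n, p), dtype=float)
        self.is_nominal = np.zeros(p, dtype=bool)
        self.n_cats = np.zeros(p, dtype=int)
        for j, spec in enumerate(schema.attributes):
            col = table.data[spec.name]
            if spec.is_numeric:
                X[:, j] = col.to_numpy(dtype=float)
            else:
                self.is_nominal[j] = True
                self.n_cats[j] = len(spec.categories)
                codes = pd.Categorical(
                    col, categories=spec.categories
                ).codes.astype(float)
                codes[codes < 0] = np.nan
                X[:, j] = codes
        self.X = X
        cls = pd.Categorical(table.classes, categories=self.class_labels)
        self.y = cls.codes.astype(np.int64)
        if (self.y < 0).any():
            raise ValueError("record with missing or unknown class label")
        self.w = table.weights.astype(float)


# ---------------------------------------------------------------------------
# entropy and split evaluation

def class_entropy(counts) -> float:
    """Shannon entropy, in bits, of a weighted class count vector.

    ``-sum p_i log2 p_i`` with ``0 * log 0 = 0``; raises on zero total.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative class count")
    total = c.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy of an (m, k) weighted count matrix, in bits."""
    tot = counts.sum(axis=1, keepdims=True)
    p = counts / np.where(tot > 0, tot, 1.0)
    plogp = np.zeros_like(p)
    mask = p > 0
    pm = p[mask]
    plogp[mask] = pm * np.log2(pm)
    return -plogp.sum(axis=1)


@dataclass(frozen=True)
class SplitTest:
    """A node test: numeric threshold (binary) or nominal (multiway)."""

    attribute: str
    threshold: float | None = None
    categories: tuple[str, ...] | None = None

    @property
    def is_numeric(self) -> bool:
        return self.threshold is not None

    def branch_labels(self) -> list[str]:
        if self.is_numeric:
            return [f"<= {self.threshold:.2f}", f"> {self.threshold:.2f}"]
        return [f"= {c}" for c in self.categories]


@dataclass(frozen=True)
class SplitEvaluation:
    """Gain-ratio bookkeeping for one candidate split.

    ``gain`` is already scaled by the known fraction ``F``; the split
    information includes the missing-weight group as an extra branch
    term, and the gain ratio is ``None`` (inadmissible) when the split
    information vanishes or the split does not partition the
    known-valued records.
    """

    attribute: str
    test: SplitTest
    known_fraction: float
    class_probs: np.ndarray
    branch_class_counts: np.ndarray  # (branches, classes), known-valued only
    entropy_total: float             # E(S) on the known-valued subset
    branch_entropies: np.ndarray
    gain: float                      # F-scaled information gain
    split_info: float
    gain_ratio: float | None

    @property
    def admissible(self) -> bool:
        return self.gain_ratio is not None and self.gain > _GAIN_EPS


def _branch_masks(comp: CompiledTable, idx: np.ndarray, test: SplitTest):
    j = comp.attr_names.index(test.attribute)
    x = comp.X[idx, j]
    missing = np.isnan(x)
    if test.is_numeric:
        masks = [(~missing) & (x <= test.threshold),
                 (~missing) & (x > test.threshold)]
    else:
        spec = comp.schema[test.attribute]
        masks = []
        for cat in test.categories:
            code = spec.categories.index(cat)
            masks.append((~missing) & (x == code))
    return masks, missing


def evaluate_split(table: FeatureTable, test: SplitTest) -> SplitEvaluation:
    """Evaluate one candidate split on a (weighted) table.

    The information gain is computed on the known-valued subset and
    scaled by the known weight fraction; a split that leaves fewer than
    two non-empty branches gets zero gain and a ``None`` gain ratio
    (signalled, not raised).
    """
    comp = CompiledTable(table)
    idx = np.arange(len(table))
    return _evaluate_split_compiled(comp, idx, comp.w, test)


def _evaluate_split_compiled(comp, idx, w, test) -> SplitEvaluation:
    k = len(comp.class_labels)
    masks, missing = _branch_masks(comp, idx, test)
    y, ww = comp.y[idx], w
    counts = np.stack([
        np.bincount(y[m], weights=ww[m], minlength=k) for m in masks
    ])
    known_counts = counts.sum(axis=0)
    W_known = known_counts.sum()
    W_total = ww.sum()
    W_miss = W_total - W_known
    F = W_known / W_total if W_total > 0 else 0.0
    branch_w = counts.sum(axis=1)
    branch_H = _entropy_rows(counts)
    H_known = class_entropy(known_counts) if W_known > 0 else 0.0
    nonempty = int((branch_w > 0).sum())
    if W_known <= 0 or nonempty < 2:
        gain = 0.0
        split_info = 0.0
        ratio = None
    else:
        gain = F * (H_known - float((branch_w * branch_H).sum()) / W_known)
        parts = np.concatenate([branch_w, [W_miss]]) if W_miss > _GAIN_EPS \
            else branch_w
        split_info = float(_entropy_rows(parts[None, :])[0])
        ratio = gain / split_info if split_info > _GAIN_EPS else None
    total_counts = np.bincount(y, weights=ww, minlength=k)
    return SplitEvaluation(
        attribute=test.attribute,
        test=test,
        known_fraction=float(F),
        class_probs=total_counts / W_total if W_total > 0 else total_counts,
        branch_class_counts=counts,
        entropy_total=H_known,
        branch_entropies=branch_H,
        gain=float(gain),
        split_info=split_info,
        gain_ratio=ratio,
    )


# -- fast candidate search ---------------------------------------------------

def _best_numeric(x, y, w, k, min_leaf, avg_gate, mdl=False):
    """Best admissible threshold for one numeric attribute at a node.

    Returns (gain_ratio, gain, split_info, threshold) or None.
    """
    known = ~np.isnan(x)
    xk, yk, wk = x[known], y[known], w[known]
    W_total = w.sum()
    W_known = wk.sum()
    if W_known <= 0 or len(xk) < 2:
        return None
    order = np.argsort(xk, kind="stable")
    xs, ys, ws = xk[order], yk[order], wk[order]
    cut = np.flatnonzero(np.diff(xs) > 0)
    if cut.size == 0:
        return None
    M = np.zeros((len(xs), k))
    M[np.arange(len(xs)), ys] = ws
    cum = M.cumsum(axis=0)
    counts_l = cum[cut]
    counts_r = cum[-1] - counts_l
    wl = counts_l.sum(axis=1)
    wr = counts_r.sum(axis=1)
    H_known = float(_entropy_rows(cum[-1][None, :])[0])
    F = W_known / W_total
    gain = F * (H_known - (wl * _entropy_rows(counts_l)
                           + wr * _entropy_rows(counts_r)) / W_known)
    W_miss = W_total - W_known
    if W_miss > _GAIN_EPS:
        parts = np.stack([wl, wr, np.full_like(wl, W_miss)], axis=1)
    else:
        parts = np.stack([wl, wr], axis=1)
    split_info = _entropy_rows(parts)  # entropy is scale-free in the counts
    admissible = (wl >= min_leaf) & (wr >= min_leaf)
    if mdl and admissible.any():
        # C4.5 R8 penalty: charge the cost of transmitting the chosen
        # threshold among the admissible candidates
        gain = gain - np.log2(int(admissible.sum())) / W_total
    valid = admissible & (gain > _GAIN_EPS) & (split_info > _GAIN_EPS)
    if avg_gate and valid.any():
        valid &= gain >= gain[valid].mean() - _GAIN_EPS
    if not valid.any():
        return None
    ratio = np.where(valid, gain / np.where(split_info > 0, split_info, 1.0),
                     -np.inf)
    best = int(np.argmax(ratio))  # first max -> lowest threshold on ties
    return float(ratio[best]), float(gain[best]), float(split_info[best]), \
        float(xs[cut[best]])


def _best_nominal(x, y, w, k, n_cat, min_leaf):
    known = ~np.isnan(x)
    xk, yk, wk = x[known].astype(int), y[known], w[known]
    W_total = w.sum()
    W_known = wk.sum()
    if W_known <= 0:
        return None
    counts = np.zeros((n_cat, k))
    np.add.at(counts, (xk, yk), wk)
    branch_w = counts.sum(axis=1)
    if int((branch_w > 0).sum()) < 2 or int((branch_w >= min_leaf).sum()) < 2:
        return None
    F = W_known / W_total
    H_known = class_entropy(counts.sum(axis=0))
    gain = F * (H_known - float((branch_w * _entropy_rows(counts)).sum())
                / W_known)
    W_miss = W_total - W_known
    parts = np.concatenate([branch_w, [W_miss]]) if W_miss > _GAIN_EPS \
        else branch_w
    split_info = float(_entropy_rows(parts[None, :])[0])
    if gain <= _GAIN_EPS or split_info <= _GAIN_EPS:
        return None
    return gain / split_info, gain, split_info, None


def best_split_for_attribute(
    table: FeatureTable,
    attribute: str,
    params: InductionParams | None = None,
) -> SplitEvaluation | None:
    """The maximum-gain-ratio admissible split on one attribute.

    Numeric attributes: thresholds are searched at midpoints of
    consecutive distinct known values and the winner is reported as the
    largest observed value not exceeding the best midpoint.  Nominal
    attributes: the single multiway split.  Returns ``None`` when no
    admissible split exists (constant attribute, all-missing, zero
    gain, or branches below the minimum leaf weight).
    """
    params = params or InductionParams()
    comp = CompiledTable(table)
    idx = np.arange(len(table))
    return _best_for_attribute_compiled(comp, idx, comp.w, attribute, params)


def _best_for_attribute_compiled(comp, idx, w, attribute, params):
    j = comp.attr_names.index(attribute)
    x = comp.X[idx, j]
    y = comp.y[idx]
    k = len(comp.class_labels)
    if comp.is_nominal[j]:
        res = _best_nominal(x, y, w, k, comp.n_cats[j],
                            params.min_leaf_weight)
        if res is None:
            return None
        test = SplitTest(attribute,
                         categories=tuple(comp.schema[attribute].categories))
    else:
        res = _best_numeric(x, y, w, k, params.min_leaf_weight,
                            params.avg_gain_gate, params.mdl_correction)
        if res is None:
            return None
        test = SplitTest(attribute, threshold=res[3])
    return _evaluate_split_compiled(comp, idx, w, test)


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    """Leaf or internal node; both carry the training class distribution."""

    dist: np.ndarray                 # weighted class counts at the node
    label_idx: int                   # majority class (ties: schema order)
    test: SplitTest | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_props: np.ndarray | None = None  # proportions among known-valued

    @property
    def is_leaf(self) -> bool:
        return self.test is None

    @property
    def weight(self) -> float:
        return float(self.dist.sum())

    @property
    def misclassified(self) -> float:
        return float(self.weight - self.dist[self.label_idx])


@dataclass
class DecisionTree:
    """An induced gain-ratio tree plus its schema and settings."""

    root: TreeNode
    schema: Schema
    attributes: tuple[str, ...]
    params: InductionParams

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.schema.class_labels)

    def n_nodes(self) -> int:
        def count(n):
            return 1 + sum(count(c) for c in n.children)
        return count(self.root)

    def n_leaves(self) -> int:
        def count(n):
            return 1 if n.is_leaf else sum(count(c) for c in n.children)
        return count(self.root)


# ---------------------------------------------------------------------------
# induction

def build_tree(
    table: FeatureTable,
    attrs: list[str] | None = None,
    params: InductionParams | None = None,
) -> DecisionTree:
    """Induce a gain-ratio tree on ``table`` restricted to ``attrs``.

    At each node the admissible split with the maximum gain ratio (ties
    broken by schema attribute order, then by the lower threshold) is
    chosen; a node becomes a leaf when pure, when its weight is below
    twice the minimum leaf weight, or when no admissible split with
    positive scaled gain exists.  Records with a missing split value
    descend all branches fractionally.  Nominal attributes are used at
    most once per path; numeric attributes may recur.
    """
    params = params or InductionParams()
    if len(table) == 0:
        raise ValueError("cannot build a tree on an empty table")
    comp = CompiledTable(table)
    return build_tree_compiled(comp, np.arange(len(table)), attrs, params,
                               base_weights=comp.w)


def build_tree_compiled(
    comp: CompiledTable,
    row_idx: np.ndarray,
    attrs: list[str] | None,
    params: InductionParams,
    base_weights: np.ndarray | None = None,
) -> DecisionTree:
    """Induction entry point on a compiled table subset (used by CV)."""
    names = comp.attr_names
    if attrs is None:
        attrs = list(names)
    else:
        unknown = [a for a in attrs if a not in names]
        if unknown:
            raise ValueError(f"unknown attribute(s) {unknown}")
        attrs = [a for a in names if a in set(attrs)]  # schema order
    if not attrs:
        raise ValueError("attrs is empty")
    if len(row_idx) == 0:
        raise ValueError("cannot build a tree on an empty table")
    attr_ids = [names.index(a) for a in attrs]
    w = (comp.w if base_weights is None else base_weights)[row_idx].copy()
    k = len(comp.class_labels)
    dist = np.bincount(comp.y[row_idx], weights=w, minlength=k)
    root = _grow(comp, np.asarray(row_idx), w, attr_ids, params,
                 int(np.argmax(dist)))
    if params.prune:
        _prune(root, params.confidence)
    return DecisionTree(root=root, schema=comp.schema,
                        attributes=tuple(attrs), params=params)


def _grow(comp, idx, w, attr_ids, params, parent_label) -> TreeNode:
    k = len(comp.class_labels)
    if len(idx) == 0:
        return TreeNode(dist=np.zeros(k), label_idx=parent_label)
    dist = np.bincount(comp.y[idx], weights=w, minlength=k)
    W = dist.sum()
    label = int(np.argmax(dist)) if W > 0 else parent_label
    node = TreeNode(dist=dist, label_idx=label)
    if W <= 0 or (dist > _GAIN_EPS).sum() <= 1:
        return node
    if W < 2 * params.min_leaf_weight:
        return node
    best = None  # (ratio, attr_id, threshold)
    for j in attr_ids:
        x = comp.X[idx, j]
        y = comp.y[idx]
        if comp.is_nominal[j]:
            res = _best_nominal(x, y, w, k, comp.n_cats[j],
                                params.min_leaf_weight)
        else:
            res = _best_numeric(x, y, w, k, params.min_leaf_weight,
                                params.avg_gain_gate, params.mdl_correction)
        if res is None:
            continue
        ratio = res[0]
        if best is None or ratio > best[0] + _TIE_EPS:
            best = (ratio, j, res[3])
    if best is None:
        return node
    _, j, threshold = best
    name = comp.attr_names[j]
    if comp.is_nominal[j]:
        test = SplitTest(name, categories=tuple(comp.schema[name].categories))
        child_attrs = [a for a in attr_ids if a != j]  # nominal used once
    else:
        test = SplitTest(name, threshold=threshold)
        child_attrs = attr_ids
    masks, missing = _branch_masks(comp, idx, test)
    branch_w = np.array([w[m].sum() for m in masks])
    W_known = branch_w.sum()
    props = branch_w / W_known
    miss_idx, miss_w = idx[missing], w[missing]
    children = []
    for m, p in zip(masks, props):
        c_idx = np.concatenate([idx[m], miss_idx])
        c_w = np.concatenate([w[m], miss_w * p])
        keep = c_w > 1e-9
        children.append(
            _grow(comp, c_idx[keep], c_w[keep], child_attrs, params, label)
        )
    node.test = test
    node.children = children
    node.branch_props = props
    return node


# -- pessimistic pruning -----------------------------------------------------

_z_cache: dict[float, float] = {}


def _add_errs(n: float, e: float, cf: float) -> float:
    """Upper confidence limit correction of the binomial training error
    (the J4.8 pessimistic estimate): returns the error count to add."""
    if n <= 0:
        return 0.0
    if cf > 0.5:
        cf = 0.5
    if e < 1:
        base = n * (1 - cf ** (1.0 / n))
        if e == 0:
            return base
        return base + e * (_add_errs(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = _z_cache.get(cf)
    if z is None:
        z = _z_cache[cf] = float(norm.ppf(1 - cf))
    f = (e + 0.5) / n
    r = (f + z * z / (2 * n)
         + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) \
        / (1 + z * z / n)
    return r * n - e


def _subtree_est_errors(node: TreeNode, cf: float) -> float:
    if node.is_leaf:
        return node.misclassified + _add_errs(node.weight,
                                              node.misclassified, cf)
    return sum(_subtree_est_errors(c, cf) for c in node.children)


def _prune(node: TreeNode, cf: float) -> None:
    if node.is_leaf:
        return
    for c in node.children:
        _prune(c, cf)
    as_leaf_err = node.misclassified
    leaf_est = as_leaf_err + _add_errs(node.weight, as_leaf_err, cf)
    subtree_est = _subtree_est_errors(node, cf)
    if leaf_est <= subtree_est + 0.1:
        node.test = None
        node.children = []
        node.branch_props = None


# ---------------------------------------------------------------------------
# classification and evaluation

def _leaf_probs(node: TreeNode, k: int) -> np.ndarray:
    s = node.dist.sum()
    if s > 0:
        return node.dist / s
    p = np.zeros(k)
    p[node.label_idx] = 1.0
    return p


def classify(tree: DecisionTree, record) -> tuple[dict[str, float], str]:
    """Class distribution and predicted class for one record.

    ``record`` is a mapping (or Series) of attribute name to value;
    missing values (``None``/NaN) descend all branches weighted by the
    branch proportions.  Ties in the final distribution are broken by
    class order in the schema.
    """
    comp_row = _encode_record(tree.schema, record)
    k = len(tree.class_labels)
    out = np.zeros(k)
    names = list(tree.schema.names)

    def route(node: TreeNode, weight: float) -> None:
        if node.is_leaf:
            out[:] += weight * _leaf_probs(node, k)
            return
        v = comp_row[names.index(node.test.attribute)]
        if np.isnan(v):
            for child, p in zip(node.children, node.branch_props):
                if p > 0:
                    route(child, weight * p)
            return
        if node.test.is_numeric:
            child = node.children[0 if v <= node.test.threshold else 1]
        else:
            child = node.children[int(v)]
        route(child, weight)

    route(tree.root, 1.0)
    pred = tree.class_labels[int(np.argmax(out))]
    return {c: float(p) for c, p in zip(tree.class_labels, out)}, pred


def _encode_record(schema: Schema, record) -> np.ndarray:
    row = np.empty(len(schema.names))
    for j, spec in enumerate(schema.attributes):
        v = record.get(spec.name) if hasattr(record, "get") \
            else record[spec.name]
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            row[j] = np.nan
        elif spec.is_numeric:
            row[j] = float(v)
        else:
            row[j] = spec.categories.index(v)
    return row


def _classify_matrix(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """(n, k) class distributions for an encoded attribute matrix."""
    n = X.shape[0]
    k = len(tree.class_labels)
    names = list(tree.schema.names)
    out = np.zeros((n, k))
    stack = [(tree.root, np.arange(n), np.ones(n))]
    while stack:
        node, idx, w = stack.pop()
        if len(idx) == 0:
            continue
        if node.is_leaf:
            out[idx] += w[:, None] * _leaf_probs(node, k)[None, :]
            continue
        j = names.index(node.test.attribute)
        x = X[idx, j]
        missing = np.isnan(x)
        if node.test.is_numeric:
            masks = [(~missing) & (x <= node.test.threshold),
                     (~missing) & (x > node.test.threshold)]
        else:
            masks = [(~missing) & (x == c)
                     for c in range(len(node.test.categories))]
        for child, m, p in zip(node.children, masks, node.branch_props):
            sel_idx = idx[m]
            sel_w = w[m]
            if missing.any() and p > 0:
                sel_idx = np.concatenate([sel_idx, idx[missing]])
                sel_w = np.concatenate([sel_w, w[missing] * p])
            if len(sel_idx):
                stack.append((child, sel_idx, sel_w))
    return out


@dataclass(frozen=True)
class EvaluationResult:
    percent_correct: float
    confusion: pd.DataFrame  # true class x predicted class, weighted

    def __repr__(self) -> str:  # compact, for reports
        return f"EvaluationResult(percent_correct={self.percent_correct:.2f})"


def evaluate(tree: DecisionTree, table: FeatureTable) -> EvaluationResult:
    """Weighted percent correct and confusion matrix on a test table."""
    if len(table) == 0:
        raise ValueError("empty test table")
    comp = CompiledTable(table)
    return evaluate_compiled(tree, comp, np.arange(len(table)))


def evaluate_compiled(tree: DecisionTree, comp: CompiledTable,
                      idx: np.ndarray) -> EvaluationResult:
    dists = _classify_matrix(tree, comp.X[idx])
    pred = np.argmax(dists, axis=1)
    y = comp.y[idx]
    w = comp.w[idx]
    labels = list(tree.class_labels)
    k = len(labels)
    correct = float(w[pred == y].sum())
    pct = 100.0 * correct / float(w.sum())
    cm = np.zeros((k, k))
    np.add.at(cm, (y, pred), w)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    return EvaluationResult(percent_correct=pct, confusion=confusion)


# ---------------------------------------------------------------------------
# rule text, shapes, DOT

def export_rules(tree: DecisionTree) -> str:
    """Indented textual rules; thresholds at 2 decimals, leaves annotated
    ``(total weight/misclassified weight)``."""
    labels = tree.class_labels
    lines: list[str] = []

    def emit(node: TreeNode, depth: int) -> None:
        ind = "  " * depth
        if node.is_leaf:
            lines.append(
                f"{ind}class: {labels[node.label_idx]} "
                f"({node.weight:.2f}/{node.misclassified:.2f})"
            )
            return
        for branch, child in zip(node.test.branch_labels(), node.children):
            lines.append(f"{ind}{node.test.attribute} {branch}:")
            emit(child, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n"


def tree_shape(tree: DecisionTree):
    """Structure summary: nested tuples of tests (thresholds rounded to
    2 decimals, as printed) and leaf class labels."""
    labels = tree.class_labels

    def shape(node: TreeNode):
        if node.is_leaf:
            return ("leaf", labels[node.label_idx])
        t = node.test
        if t.is_numeric:
            return ("num", t.attribute, round(t.threshold, 2),
                    tuple(shape(c) for c in node.children))
        return ("nom", t.attribute,
                tuple((c, shape(ch))
                      for c, ch in zip(t.categories, node.children)))

    return shape(tree.root)


def parse_rules(text: str):
    """Parse rule text produced by :func:`export_rules` back into the
    shape structure of :func:`tree_shape` (a structural round-trip; leaf
    weights are not recovered)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]

    def depth_of(line: str) -> int:
        return (len(line) - len(line.lstrip(" "))) // 2

    pos = 0

    def parse(depth: int):
        nonlocal pos
        line = lines[pos].strip()
        if line.startswith("class: "):
            pos += 1
            label = line[len("class: "):].split(" (")[0]
            return ("leaf", label)
        branches = []
        attr = None
        kind = None
        while pos < len(lines) and depth_of(lines[pos]) == depth:
            header = lines[pos].strip()
            if header.startswith("class: "):
                break
            body = header.rstrip(":")
            if " <= " in body:
                attr, val = body.split(" <= ")
                kind, op = "num", ("le", float(val))
            elif " > " in body:
                attr, val = body.split(" > ")
                kind, op = "num", ("gt", float(val))
            else:
                attr, val = body.split(" = ")
                kind, op = "nom", ("eq", val)
            pos += 1
            child = parse(depth + 1)
            branches.append((op, child))
        if kind == "num":
            thr = branches[0][0][1]
            return ("num", attr, round(thr, 2),
                    tuple(c for _, c in branches))
        return ("nom", attr, tuple((op[1], c) for op, c in branches))

    return parse(0)


def split_attributes(tree: DecisionTree) -> set[str]:
    """Names of attributes appearing in any internal node."""
    found: set[str] = set()

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        found.add(node.test.attribute)
        for c in node.children:
            walk(c)

    walk(tree.root)
    return found


def to_dot(tree: DecisionTree) -> str:
    """Graphviz DOT source of the tree (attributes as ellipses, classes
    as boxes, branch labels on the edges)."""
    labels = tree.class_labels
    lines = ["digraph pollentree {", "  node [fontname=\"Helvetica\"];"]
    counter = [0]

    def emit(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            lines.append(
                f'  n{nid} [shape=box, label="{labels[node.label_idx]}\\n'
                f'({node.weight:.2f}/{node.misclassified:.2f})"];'
            )
            return nid
        lines.append(
            f'  n{nid} [shape=ellipse, label="{node.test.attribute}"];'
        )
        for branch, child in zip(node.test.branch_labels(), node.children):
            cid = emit(child)
            lines.append(f'  n{nid} -> n{cid} [label="{branch}"];')
        return nid

    emit(tree.root)
    lines.append("}")
    return "\n".join(lines) + "\n"
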