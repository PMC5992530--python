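"""Independent brute-force oracles for split-search verification.

Everything here is computed directly from the definitions with explicit
loops — deliberately sharing no code with the induction fast path.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from pollentree import AttributeSpec, FeatureTable, InductionParams, Schema

TIE_EPS = 1e-10


def entropy(counts) -> float:
    total = float(sum(counts))
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def brute_force_best_split(table: FeatureTable, params: InductionParams):
    """Exhaustively enumerate every admissible split and return the
    argmax of the (MDL-corrected, F-scaled) gain ratio as
    ``(attribute, threshold)``; ties by schema order then lower
    threshold.  Assumes no missing values and numeric attributes."""
    labels = list(table.schema.class_labels)
    y = [labels.index(v) for v in table.classes]
    w = list(table.weights)
    k = len(labels)
    W = sum(w)
    total_counts = [0.0] * k
    for yi, wi in zip(y, w):
        total_counts[yi] += wi
    H_total = entropy(total_counts)
    best = None  # (ratio, attr_index, threshold)
    for ai, spec in enumerate(table.schema.attributes):
        x = [float(v) for v in table.data[spec.name]]
        values = sorted(set(x))
        candidates = []
        for lo, hi in zip(values, values[1:]):
            mid = (lo + hi) / 2.0
            left = [0.0] * k
            right = [0.0] * k
            for xi, yi, wi in zip(x, y, w):
                (left if xi <= mid else right)[yi] += wi
            wl, wr = sum(left), sum(right)
            if wl < params.min_leaf_weight or wr < params.min_leaf_weight:
                continue
            gain = H_total - (wl * entropy(left) + wr * entropy(right)) / W
            split_info = entropy([wl, wr])
            candidates.append((lo, gain, split_info))
        if not candidates:
            continue
        n_cand = len(candidates)
        for thr, gain, split_info in candidates:
            if params.mdl_correction:
                gain = gain - math.log2(n_cand) / W
            if gain <= 1e-12 or split_info <= 1e-12:
                continue
            ratio = gain / split_info
            if best is None or ratio > best[0] + TIE_EPS:
                best = (ratio, ai, thr)
            elif abs(ratio - best[0]) <= TIE_EPS and ai == best[1] \
                    and thr < best[2]:
                best = (ratio, ai, thr)
    if best is None:
        return None
    return table.schema.attributes[best[1]].name, best[2]


def random_numeric_table(rng: np.random.Generator, max_records: int = 8,
                         max_attrs: int = 3) -> FeatureTable:
    """A small random all-numeric table with 2-3 classes."""
    n = int(rng.integers(4, max_records + 1))
    p = int(rng.integers(1, max_attrs + 1))
    k = int(rng.integers(2, 4))
    labels = tuple("abc"[:k])
    attrs = tuple(
        AttributeSpec(f"x{j}", "continuous") for j in range(p)
    )
    schema = Schema(attrs, class_name="cls", class_labels=labels)
    data = {
        f"x{j}": rng.integers(0, 5, size=n).astype(float) for j in range(p)
    }
    data["cls"] = [labels[i] for i in rng.integers(0, k, size=n)]
    return FeatureTable(schema, pd.DataFrame(data))
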