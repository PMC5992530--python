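"""Weighted feature tables (the training set S and its subsets)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import Schema

__all__ = ["FeatureTable", "DerivedInconsistencyWarning", "TableValidationError"]

# measured/calculated fields may disagree by rounding; tolerance in µm
DERIVED_TOL_UM = 0.01


class DerivedInconsistencyWarning(UserWarning):
    """A derived attribute disagrees with its constituents."""


class TableValidationError(ValueError):
    """A record value violates its attribute spec."""


@dataclass
class FeatureTable:
    """Records of morphological attribute values with class labels and weights.

    ``data`` holds one column per schema attribute plus the class column
    (class last).  Numeric columns are float64 with NaN for missing;
    nominal columns and the class column are object/str with NaN/None
    for missing.  ``weights`` is a positive float per record (C4.5-style
    fractional instance weights; 1.0 for ordinary records).
    """

    schema: Schema
    data: pd.DataFrame
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(len(self.data), dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.data):
            raise TableValidationError("weights length does not match records")
        cols = self.schema.columns()
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise TableValidationError(f"missing columns: {missing}")
        self.data = self.data.loc[:, cols].reset_index(drop=True)
        self.validate()

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def classes(self) -> pd.Series:
        return self.data[self.schema.class_name]

    def class_counts(self) -> pd.Series:
        return self.classes.value_counts()

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def equals(self, other: "FeatureTable") -> bool:
        """Value equality including missing pattern and weights."""
        if self.schema.columns() != other.schema.columns():
            return False
        if not np.allclose(self.weights, other.weights):
            return False
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        for c in a.columns:
            xa, xb = a[c], b[c]
            if xa.dtype.kind == "f" or xb.dtype.kind == "f":
                ok = (xa.isna() == xb.isna()).all() and np.allclose(
                    xa.fillna(0.0).astype(float), xb.fillna(0.0).astype(float),
                    rtol=0, atol=1e-9,
                )
            else:
                ok = (xa.fillna("?") == xb.fillna("?")).all()
            if not ok:
                return False
        return True

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check kinds, categories, labels and weights; warn on derived
        inconsistencies (measured tables may carry rounding error)."""
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise TableValidationError("weights must be positive and finite")
        for spec in self.schema.attributes:
            col = self.data[spec.name]
            if spec.is_numeric:
                vals = pd.to_numeric(col, errors="coerce")
                bad = col.notna() & vals.isna()
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise TableValidationError(
                        f"row {row}: non-numeric value {col.iloc[row]!r} "
                        f"in numeric attribute {spec.name!r}"
                    )
                self.data[spec.name] = vals.astype(float)
                if spec.kind == "count":
                    known = vals.dropna()
                    if len(known) and (
                        (known < 0).any() or (known != known.round()).any()
                    ):
                        raise TableValidationError(
                            f"attribute {spec.name!r}: counts must be "
                            "non-negative integers"
                        )
            else:
                known = col.dropna()
                bad = ~known.isin(spec.categories)
                if bad.any():
                    row = int(known.index[np.flatnonzero(bad.to_numpy())[0]])
                    raise TableValidationError(
                        f"row {row}: unknown category {known.loc[row]!r} "
                        f"for nominal attribute {spec.name!r}"
                    )
        labels = self.classes.dropna()
        bad = ~labels.isin(self.schema.class_labels)
        if bad.any():
            row = int(labels.index[np.flatnonzero(bad.to_numpy())[0]])
            raise TableValidationError(
                f"row {row}: unknown class label {labels.loc[row]!r}"
            )
        self._warn_derived()

    def _warn_derived(self) -> None:
        for spec in self.schema.attributes:
            if not spec.derived_from:
                continue
            parts = [self.data[d] for d in spec.derived_from]
            if spec.derivation == "difference":
                expect = parts[0] - parts[1]
                tol = DERIVED_TOL_UM
            else:
                expect = sum(parts[1:], parts[0].copy())
                tol = 0.0
            have = self.data[spec.name]
            ok_rows = have.notna() & expect.notna()
            if not ok_rows.any():
                continue
            dev = (have[ok_rows] - expect[ok_rows]).abs()
            bad = dev > tol + 1e-12
            if bad.any():
                n = int(bad.sum())
                row = int(dev.index[np.flatnonzero(bad.to_numpy())[0]])
                warnings.warn(
                    f"{spec.name}: {n} record(s) inconsistent with "
                    f"{'-'.join(spec.derived_from)} (first at row {row}); "
                    "records kept",
                    DerivedInconsistencyWarning,
                    stacklevel=3,
                )
        # sanity warning: axes order
        if "min_axis" in self.schema and "max_axis" in self.schema:
            lo, hi = self.data["min_axis"], self.data["max_axis"]
            bad = lo.notna() & hi.notna() & (hi < lo - 1e-12)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                warnings.warn(
                    f"max_axis < min_axis in {int(bad.sum())} record(s) "
                    f"(first at row {row}); records kept",
                    DerivedInconsistencyWarning,
                    stacklevel=3,
                )

    # -- helpers ---------------------------------------------------------
    def take(self, indices: np.ndarray, weights: np.ndarray | None = None) -> "FeatureTable":
        """Row subset (optionally re-weighted), preserving the schema."""
        df = self.data.iloc[np.asarray(indices)].reset_index(drop=True)
        w = self.weights[np.asarray(indices)] if weights is None else weights
        return FeatureTable(self.schema, df, np.asarray(w, dtype=float).copy())
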