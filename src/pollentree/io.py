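"""Reading and writing feature tables as CSV or ARFF.

Both formats use ``?`` as the missing-value token (WEKA convention; an
empty CSV cell is accepted on input as well).  ARFF files declare the
nominal category lists and put the class attribute last; instance
weights, when not all 1, are carried in the WEKA ``{w}`` suffix syntax
(ARFF) or in a ``_weight`` column (CSV).
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import AttributeSpec, Schema
from .table import FeatureTable, TableValidationError

__all__ = ["read_table", "write_table", "ParseError"]

MISSING = "?"
WEIGHT_COL = "_weight"


class ParseError(ValueError):
    """Unparseable input file (bad value, unknown column/category...)."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "arff"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "arff" if suffix == ".arff" else "csv"


# ---------------------------------------------------------------------------
# reading

def read_table(
    path: str | Path,
    format: str | None = None,
    schema: Schema | None = None,
) -> FeatureTable:
    """Read a validated feature table.

    CSV input is checked against ``schema`` (the default morphometry
    schema when omitted); ARFF input carries its own attribute
    declarations, which must agree with ``schema`` when one is given.
    Derived-attribute inconsistencies are reported as warnings, not
    errors.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(Path(path), schema)
    return _read_arff(Path(path), schema)


def _read_csv(path: Path, schema: Schema | None) -> FeatureTable:
    from .schema import default_schema

    schema = schema or default_schema()
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False,
        na_values=[MISSING, ""],
    )
    has_w = WEIGHT_COL in df.columns
    expected = schema.columns()
    got = [c for c in df.columns if c != WEIGHT_COL]
    unknown = [c for c in got if c not in expected]
    if unknown:
        raise ParseError(f"{path}: unknown attribute column(s) {unknown}")
    absent = [c for c in expected if c not in got]
    if absent:
        raise ParseError(f"{path}: missing column(s) {absent}")
    weights = None
    if has_w:
        weights = pd.to_numeric(df[WEIGHT_COL], errors="coerce").to_numpy()
        if np.isnan(weights).any():
            row = int(np.flatnonzero(np.isnan(weights))[0])
            raise ParseError(f"{path}: row {row}: bad weight")
        df = df.drop(columns=[WEIGHT_COL])
    try:
        return FeatureTable(schema, df, weights)
    except TableValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


_ARFF_ATTR = re.compile(
    r"@attribute\s+(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.IGNORECASE
)


def _read_arff(path: Path, schema: Schema | None) -> FeatureTable:
    names: list[str] = []
    kinds: list[str] = []
    cats: list[tuple[str, ...] | None] = []
    rows: list[list[str | None]] = []
    weights: list[float] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    m = _ARFF_ATTR.match(line)
                    if not m:
                        raise ParseError(f"{path}:{lineno}: bad @attribute line")
                    name = next(g for g in m.groups()[:3] if g is not None)
                    decl = m.group(4).strip()
                    names.append(name)
                    if decl.startswith("{"):
                        levels = tuple(
                            s.strip().strip("'\"")
                            for s in decl.strip("{} \t").split(",")
                        )
                        kinds.append("nominal")
                        cats.append(levels)
                    elif decl.lower() in ("numeric", "real", "integer"):
                        kinds.append("numeric")
                        cats.append(None)
                    else:
                        raise ParseError(
                            f"{path}:{lineno}: unsupported type {decl!r}"
                        )
                elif low.startswith("@data"):
                    in_data = True
                else:
                    raise ParseError(f"{path}:{lineno}: unexpected {line!r}")
                continue
            w = 1.0
            m = re.search(r",\s*\{([^}]*)\}\s*$", line)
            if m:
                w = float(m.group(1))
                line = line[: m.start()]
            vals = [v.strip().strip("'\"") for v in line.split(",")]
            if len(vals) != len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(names)} values, "
                    f"got {len(vals)}"
                )
            rows.append([None if v == MISSING or v == "" else v for v in vals])
            weights.append(w)
    if not names:
        raise ParseError(f"{path}: no @attribute declarations")
    if schema is None:
        schema = _schema_from_arff(names, kinds, cats)
    else:
        if names != schema.columns():
            raise ParseError(
                f"{path}: attribute declarations do not match schema"
            )
    df = pd.DataFrame(rows, columns=names, dtype=object)
    try:
        return FeatureTable(schema, df, np.asarray(weights))
    except TableValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _schema_from_arff(names, kinds, cats) -> Schema:
    """Build a minimal schema from ARFF declarations (class = last)."""
    from .schema import default_schema

    default = default_schema()
    if names == default.columns():
        # reuse full metadata (derivations, measurement groups)
        return default
    attrs = []
    for name, kind, c in zip(names[:-1], kinds[:-1], cats[:-1]):
        if kind == "nominal":
            attrs.append(AttributeSpec(name, "nominal", categories=tuple(c)))
        else:
            attrs.append(AttributeSpec(name, "continuous"))
    if kinds[-1] != "nominal":
        raise ParseError("class attribute (last) must be nominal")
    return Schema(tuple(attrs), class_name=names[-1],
                  class_labels=tuple(cats[-1]))


# ---------------------------------------------------------------------------
# writing

def _fmt_value(v, spec: AttributeSpec | None) -> str:
    if v is None or pd.isna(v):
        return MISSING
    if spec is not None and spec.kind == "count":
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        f = float(v)
        return repr(f) if f != int(f) else str(int(f))
    return str(v)


def write_table(
    table: FeatureTable,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a feature table; missing values become ``?``."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(table, Path(path))
    else:
        _write_arff(table, Path(path))


def _write_csv(table: FeatureTable, path: Path) -> None:
    cols = table.schema.columns()
    carry_w = not np.allclose(table.weights, 1.0)
    buf = _io.StringIO()
    header = cols + ([WEIGHT_COL] if carry_w else [])
    buf.write(",".join(header) + "\n")
    specs = {a.name: a for a in table.schema.attributes}
    for i in range(len(table)):
        row = [
            _fmt_value(table.data[c].iloc[i], specs.get(c)) for c in cols
        ]
        if carry_w:
            row.append(repr(float(table.weights[i])))
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _write_arff(table: FeatureTable, path: Path) -> None:
    schema = table.schema
    buf = _io.StringIO()
    buf.write("@relation pollen_morphometry\n\n")
    for a in schema.attributes:
        if a.kind == "nominal":
            buf.write(f"@attribute {a.name} {{{','.join(a.categories)}}}\n")
        else:
            buf.write(f"@attribute {a.name} numeric\n")
    buf.write(
        f"@attribute {schema.class_name} "
        f"{{{','.join(schema.class_labels)}}}\n"
    )
    buf.write("\n@data\n")
    carry_w = not np.allclose(table.weights, 1.0)
    specs = {a.name: a for a in schema.attributes}
    cols = schema.columns()
    for i in range(len(table)):
        row = [_fmt_value(table.data[c].iloc[i], specs.get(c)) for c in cols]
        line = ",".join(row)
        if carry_w:
            line += f", {{{float(table.weights[i])!r}}}"
        buf.write(line + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
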