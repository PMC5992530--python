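"""Schema fidelity and CSV/ARFF round-trips with '?' missing values."""

import warnings

import numpy as np
import pytest

from pollentree import (
    DerivedInconsistencyWarning,
    ParseError,
    default_schema,
    read_table,
    write_table,
)
from pollentree.table import FeatureTable, TableValidationError


def test_schema_has_13_attributes_plus_class():
    schema = default_schema()
    assert len(schema.attributes) == 13
    assert schema.class_name == "taxon"
    assert schema.class_labels == ("Betula", "Corylus", "Alnus")
    position = schema["position"]
    assert position.kind == "nominal" and len(position.categories) == 5


def test_co_measured_attributes_share_groups():
    schema = default_schema()
    assert (schema["max_oncus_width"].measurement_group
            == schema["min_oncus_width"].measurement_group)
    assert (schema["max_oncus_height"].measurement_group
            == schema["min_oncus_height"].measurement_group)
    assert set(schema["n_pores"].derived_from) == {
        "n_top_pores", "n_lateral_pores", "n_oblique_pores"}
    assert set(schema["axes_diff"].derived_from) == {"max_axis", "min_axis"}


@pytest.mark.parametrize("fmt", ["csv", "arff"])
def test_round_trip_preserves_values_and_missingness(default_table, tmp_path,
                                                     fmt):
    path = tmp_path / f"table.{fmt}"
    write_table(default_table, path, format=fmt)
    back = read_table(path, format=fmt)
    assert back.equals(default_table)
    # the missing token is literally "?"
    text = path.read_text()
    assert "?" in text
    assert "nan" not in text.lower().replace("nanometer", "")


def test_round_trip_preserves_fractional_weights(default_table, tmp_path):
    weighted = default_table.take(
        np.arange(6), weights=np.array([1.0, 0.5, 2.25, 1.0, 0.75, 3.0]))
    for fmt in ("csv", "arff"):
        path = tmp_path / f"w.{fmt}"
        write_table(weighted, path, format=fmt)
        assert read_table(path, format=fmt).equals(weighted)


def test_empty_table_writes_header_only(default_table, tmp_path):
    empty = default_table.take(np.array([], dtype=int))
    path = tmp_path / "empty.csv"
    write_table(empty, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1  # header row only
    assert read_table(path).n_records == 0
    arff = tmp_path / "empty.arff"
    write_table(empty, arff)
    assert read_table(arff).n_records == 0


def test_unknown_category_is_a_parse_error(default_table, tmp_path):
    path = tmp_path / "bad.csv"
    write_table(default_table, path)
    text = path.read_text().replace(",P,", ",Q,", 1)
    path.write_text(text)
    with pytest.raises(ParseError, match="row \\d+"):
        read_table(path)


def test_non_numeric_value_is_a_parse_error(default_table, tmp_path):
    path = tmp_path / "bad.csv"
    write_table(default_table, path)
    lines = path.read_text().splitlines()
    cells = lines[1].split(",")
    cells[0] = "abc"
    lines[1] = ",".join(cells)
    path.write_text("\n".join(lines))
    with pytest.raises(ParseError, match="non-numeric"):
        read_table(path)


def test_unknown_column_is_a_parse_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("bogus,taxon\n1.0,Betula\n")
    with pytest.raises(ParseError):
        read_table(path)


def test_axes_inconsistency_warns_but_keeps_record(default_table, tmp_path):
    path = tmp_path / "warn.csv"
    df = default_table.data.copy()
    df.loc[0, "max_axis"] = df.loc[0, "min_axis"] - 5.0  # max < min
    write_table(FeatureTable(default_table.schema, df), path)
    with pytest.warns(DerivedInconsistencyWarning):
        table = read_table(path)
    assert table.n_records == default_table.n_records


def test_weights_must_be_positive(default_table):
    with pytest.raises(TableValidationError):
        default_table.take(np.arange(3), weights=np.array([1.0, 0.0, 1.0]))


def test_arff_declares_nominal_categories_and_class_last(default_table,
                                                         tmp_path):
    path = tmp_path / "t.arff"
    write_table(default_table, path)
    text = path.read_text()
    attr_lines = [l for l in text.splitlines()
                  if l.lower().startswith("@attribute")]
    assert len(attr_lines) == 14
    assert "position {P,E,I,NE,NP}" in attr_lines[-2]
    assert attr_lines[-1].startswith("@attribute taxon {")
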