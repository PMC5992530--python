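import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pollentree import (
    AttributeSpec,
    FeatureTable,
    Schema,
    default_config,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_table() -> FeatureTable:
    """One 225-grain synthetic dataset (75 per taxon), fixed seed."""
    return generate_dataset(default_config(seed=11))


@pytest.fixture()
def two_class_schema() -> Schema:
    return Schema(
        (AttributeSpec("x", "continuous"),),
        class_name="cls",
        class_labels=("a", "b"),
    )


def make_xy_table(schema: Schema, xs, ys, weights=None) -> FeatureTable:
    df = pd.DataFrame({"x": [np.nan if v is None else float(v) for v in xs],
                       schema.class_name: list(ys)})
    return FeatureTable(schema, df, weights)


@pytest.fixture()
def separable_table() -> FeatureTable:
    """Two classes perfectly separated by one attribute; second constant."""
    schema = Schema(
        (AttributeSpec("x", "continuous"), AttributeSpec("z", "continuous")),
        class_name="cls",
        class_labels=("a", "b"),
    )
    n = 10
    df = pd.DataFrame({
        "x": [1.0] * n + [5.0] * n,
        "z": [2.0] * (2 * n),
        "cls": ["a"] * n + ["b"] * n,
    })
    return FeatureTable(schema, df)
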