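"""Synthetic morphometry generator: design counts, derived-attribute
identities, joint missingness, determinism and calibration."""

import numpy as np
import pytest
from dataclasses import replace

from pollentree import (
    ConfigError,
    SyntheticConfig,
    TruncNormal,
    default_config,
    generate_dataset,
)


@pytest.fixture(scope="module")
def table():
    return generate_dataset(default_config(seed=3))


def test_default_design_is_75_grains_per_taxon(table):
    assert len(table) == 225
    counts = table.class_counts()
    assert set(counts.index) == {"Betula", "Corylus", "Alnus"}
    assert (counts == 75).all()


def test_same_seed_gives_bit_identical_tables():
    a = generate_dataset(default_config(seed=9))
    b = generate_dataset(default_config(seed=9))
    assert a.equals(b)


def test_different_seeds_differ():
    a = generate_dataset(default_config(seed=9))
    b = generate_dataset(default_config(seed=10))
    assert not a.equals(b)


def test_derived_attributes_are_exact(table):
    d = table.data
    assert np.allclose(d.axes_diff, d.max_axis - d.min_axis)
    assert np.array_equal(
        d.n_pores, d.n_top_pores + d.n_lateral_pores + d.n_oblique_pores)
    for col in ("min_axis", "max_axis", "axes_diff", "wall"):
        assert (d[col] > 0).all()


def test_oncus_fields_missing_jointly(table):
    d = table.data
    oncus = d[["min_oncus_height", "max_oncus_height",
               "min_oncus_width", "max_oncus_width"]]
    n_missing = oncus.isna().sum(axis=1)
    assert set(n_missing.unique()) <= {0, 4}


def test_oncus_ordering_where_present(table):
    d = table.data
    known = d.max_oncus_width.notna()
    assert (d.min_oncus_width[known] <= d.max_oncus_width[known]).all()
    assert (d.min_oncus_height[known] <= d.max_oncus_height[known]).all()
    assert (d.min_oncus_width[known] > 0).all()


def test_probability_vectors_sum_to_one():
    for prof in default_config().profiles:
        assert sum(prof.pore_tuple_dist.values()) == pytest.approx(1, abs=1e-9)
        assert sum(prof.position_dist.values()) == pytest.approx(1, abs=1e-9)


def test_calibration_fractions_at_large_n():
    """The narrative fractions the profiles are calibrated to, checked
    by Monte Carlo at 2000 grains per taxon (3 pp slack)."""
    d = generate_dataset(default_config(n_per_taxon=2000, seed=21)).data
    alnus = d[d.taxon == "Alnus"]
    corylus = d[d.taxon == "Corylus"]
    betula = d[(d.taxon == "Betula") & d.max_oncus_width.notna()]
    frac_alnus = (alnus.n_pores > 3).mean()
    assert 0.80 <= frac_alnus <= 0.95
    assert frac_alnus >= 0.85 - 0.03
    assert ((corylus.max_axis > 24.39)
            & (corylus.min_axis > 22.24)).mean() >= 0.85 - 0.03
    assert ((betula.max_oncus_width <= 10.19)
            & (betula.axes_diff < 2.92)).mean() >= 0.80 - 0.03
    assert d.max_oncus_width.isna().mean() == pytest.approx(0.1, abs=0.03)


def test_invalid_configs_name_the_offending_field():
    cfg = default_config()
    bad = replace(cfg.profiles[0],
                  pore_tuple_dist={(0, 3, 0): 0.5, (1, 2, 0): 0.4})
    with pytest.raises(ConfigError, match="Betula.*pore_tuple_dist"):
        SyntheticConfig(profiles=(bad, *cfg.profiles[1:])).validate()
    bad = replace(cfg.profiles[1], oncus_missing_prob=1.5)
    with pytest.raises(ConfigError, match="Corylus.*oncus_missing_prob"):
        SyntheticConfig(profiles=(cfg.profiles[0], bad,
                                  cfg.profiles[2])).validate()
    with pytest.raises(ConfigError, match="n_per_taxon"):
        SyntheticConfig(profiles=cfg.profiles, n_per_taxon=0).validate()
    with pytest.raises(ConfigError, match="pore_tuple_dist"):
        replace(cfg.profiles[0],
                pore_tuple_dist={(0, 1, 0): 1.0}).validate()  # total < 2


def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(n_per_taxon=10, seed=4)
    path = tmp_path / "config.yaml"
    cfg.save(path)
    loaded = SyntheticConfig.load(path)
    assert loaded.n_per_taxon == 10 and loaded.seed == 4
    assert generate_dataset(loaded).equals(generate_dataset(cfg))


def test_truncnormal_respects_bounds():
    rng = np.random.default_rng(0)
    draws = TruncNormal(2.0, 1.5, lower=0.5, upper=3.0).draw(rng, 500)
    assert draws.min() >= 0.5 and draws.max() <= 3.0
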