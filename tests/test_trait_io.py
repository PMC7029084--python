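"""Trait-table reading, min/max harmonization, subsetting, log pairing."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lhinvar.trait_io import (
    GroupSpec,
    InsufficientSample,
    TraitTable,
    harmonize_min_max,
    normalize_species,
    paired_log10,
    read_trait_table,
    subset_group,
    write_trait_table,
)

SCHEMA = {
    "species": "Species",
    "group": "Order",
    "body_mass": "BM",
    "traits": {"clutch_size": "CS"},
    "units": {"body_mass": "g", "clutch_size": "count"},
}


def write_csv(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestRead:
    def test_identity_passthrough(self, tmp_path):
        p = write_csv(tmp_path,
                      "Species,Order,BM,CS\nA a,Anura,10,5\n"
                      "B b,Anura,20,6\nC c,Caudata,30,7\n")
        t = read_trait_table(p, SCHEMA)
        assert len(t) == 3
        assert t.trait_names == ["clutch_size"]
        assert t.units["clutch_size"] == "count"
        np.testing.assert_allclose(t.df["body_mass"], [10, 20, 30])

    def test_nonpositive_and_nonnumeric_become_missing(self, tmp_path, caplog):
        p = write_csv(tmp_path,
                      "Species,Order,BM,CS\nA a,Anura,0,5\n"
                      "B b,Anura,20,x\nC c,Anura,30,7\n")
        with caplog.at_level(logging.WARNING):
            t = read_trait_table(p, SCHEMA)
        assert len(t) == 3  # row count preserved
        assert np.isnan(t.df["body_mass"].iloc[0])
        assert np.isnan(t.df["clutch_size"].iloc[1])
        assert "non-positive" in caplog.text and "non-numeric" in caplog.text

    def test_duplicate_species_rejected(self, tmp_path):
        p = write_csv(tmp_path,
                      "Species,Order,BM,CS\nRana temporaria,Anura,10,5\n"
                      "Rana  temporaria ,Anura,20,6\n")
        with pytest.raises(ValueError, match="Rana temporaria"):
            read_trait_table(p, SCHEMA)

    def test_missing_species_column_is_hard_error(self, tmp_path):
        p = write_csv(tmp_path, "Sp,BM\nA,1\n")
        with pytest.raises(ValueError, match="species"):
            read_trait_table(p, SCHEMA)

    def test_roundtrip_preserves_values_and_missingness(self, tmp_path):
        p = write_csv(tmp_path,
                      "Species,Order,BM,CS\nA a,Anura,10,\n"
                      "B b,Caudata,NA,6.25\nC c,Anura,30,7\n")
        t1 = read_trait_table(p, SCHEMA)
        out = tmp_path / "rt.csv"
        write_trait_table(t1, out)
        t2 = read_trait_table(out, {
            "species": "species", "group": "group", "body_mass": "body_mass",
            "traits": {"clutch_size": "clutch_size"},
        })
        pd.testing.assert_frame_equal(t1.df, t2.df)


def test_normalize_species_collapses_whitespace():
    assert normalize_species("  Rana   temporaria ") == "Rana temporaria"


class TestHarmonize:
    def make(self, lo, hi):
        df = pd.DataFrame({
            "species": [f"S{i}" for i in range(len(lo))],
            "group": "G",
            "body_mass": 10.0,
            "cs_min": lo, "cs_max": hi,
        })
        return TraitTable(df, {"cs_min": "count", "cs_max": "count"})

    @pytest.mark.parametrize("lo,hi,expect", [
        (10.0, 20.0, 15.0),          # plain mean
        (7.0, np.nan, 7.0),          # single-value fallback
        (np.nan, np.nan, np.nan),    # both missing stays missing
        (20.0, 10.0, 15.0),          # reversed pair: order-insensitive mean
    ])
    def test_mean_semantics(self, lo, hi, expect):
        t = harmonize_min_max(self.make([lo], [hi]),
                              [("cs_min", "cs_max", "clutch_size")])
        got = t.df["clutch_size"].iloc[0]
        assert (np.isnan(expect) and np.isnan(got)) or got == expect
        assert "cs_min" not in t.df.columns

    def test_reversed_pair_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            harmonize_min_max(self.make([20.0], [10.0]),
                              [("cs_min", "cs_max", "clutch_size")])
        assert "min > max" in caplog.text

    def test_idempotent(self):
        pairs = [("cs_min", "cs_max", "clutch_size")]
        t1 = harmonize_min_max(self.make([10.0, 4.0], [20.0, np.nan]), pairs)
        t2 = harmonize_min_max(t1, pairs)
        pd.testing.assert_frame_equal(t1.df, t2.df)


class TestSubset:
    def test_pooled_union(self, small_table):
        spec = GroupSpec.of("amphibians", "Anura", "Caudata", "Gymnophiona")
        assert len(subset_group(small_table, spec)) == 6

    def test_single_order(self, small_table):
        assert len(subset_group(small_table, GroupSpec.of("Anura"))) == 3

    def test_empty_subset_warns(self, small_table, caplog):
        with caplog.at_level(logging.WARNING):
            t = subset_group(small_table, GroupSpec.of("Reptilia"))
        assert len(t) == 0 and "empty" in caplog.text

    def test_empty_member_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("bad", frozenset())


class TestPairedLog10:
    def test_log10_values(self, small_table):
        x, y, sp = paired_log10(small_table, "clutch_size")
        # species 3 lacks the trait, species 6 lacks mass: 4 complete pairs
        assert len(sp) == 4
        np.testing.assert_allclose(x, np.log10([10, 100, 5, 50]))
        np.testing.assert_allclose(y, np.log10([20, 200, 8, 80]))

    def test_insufficient_pairs_flagged(self, small_table):
        with pytest.raises(InsufficientSample):
            paired_log10(small_table, "clutch_size", min_n=5)

    @given(st.integers(0, 6))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_length_bounded_by_each_margin(self, k):
        df = pd.DataFrame({
            "species": [f"S{i}" for i in range(6)],
            "group": "G",
            "body_mass": [1.0] * k + [np.nan] * (6 - k),
            "t": [2.0, np.nan] * 3,
        })
        t = TraitTable(df, {})
        try:
            x, y, sp = paired_log10(t, "t")
        except InsufficientSample:
            return
        n_mass = df["body_mass"].notna().sum()
        n_tr = df["t"].notna().sum()
        assert len(x) == len(y) <= min(n_mass, n_tr)
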