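"""Community-table I/O, filtering, rarefaction, and covariate handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mycassembly.tables import (
    CommunityTable, TableError, read_community_table, write_community_table,
    filter_low_count_taxa, rarefy, relative_abundance, derive_aridity,
    collinearity_prune,
)


class TestIO:
    def test_tsv_round_trip_identity(self, tiny_table, tmp_path):
        p = tmp_path / "table.tsv"
        write_community_table(tiny_table, p)
        back = read_community_table(p)
        assert back.sample_ids == tiny_table.sample_ids
        assert back.taxon_ids == tiny_table.taxon_ids
        np.testing.assert_array_equal(back.counts, tiny_table.counts)
        np.testing.assert_array_equal(back.depth, [10, 5])

    def test_biom_round_trip(self, tiny_table, tmp_path):
        import biom

        bt = biom.Table(tiny_table.counts.T, tiny_table.taxon_ids,
                        tiny_table.sample_ids)
        p = tmp_path / "table.biom"
        p.write_text(bt.to_json("test"))
        back = read_community_table(p, format="biom")
        np.testing.assert_array_equal(back.counts, tiny_table.counts)

    def test_duplicate_taxon_id_named_in_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("#ASV ID\ts1\ts2\ntaxA\t1\t2\ntaxA\t3\t4\n")
        with pytest.raises(TableError, match="taxA"):
            read_community_table(p)

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("#ASV ID\ts1\ts2\n")
        with pytest.raises(TableError, match="no taxa"):
            read_community_table(p)

    def test_non_integer_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#ASV ID\ts1\ntaxA\t1.5\n")
        with pytest.raises(TableError, match="s1"):
            read_community_table(p)


class TestFilter:
    def test_threshold_is_strictly_less_than(self):
        # totals 7, 8, 100 -> the 7-read taxon goes, 8 stays
        t = CommunityTable(np.array([[3, 4, 60], [4, 4, 40]]),
                           ["a", "b"], ["low", "edge", "high"])
        out = filter_low_count_taxa(t, min_reads=8)
        assert out.taxon_ids == ["edge", "high"]
        assert out.sample_ids == t.sample_ids

    def test_zero_threshold_is_identity(self, tiny_table):
        out = filter_low_count_taxa(tiny_table, min_reads=0)
        np.testing.assert_array_equal(out.counts, tiny_table.counts)

    def test_all_taxa_removed_sets_warning(self, tiny_table):
        out = filter_low_count_taxa(tiny_table, min_reads=1000)
        assert out.n_taxa == 0
        assert out.warning is not None


class TestRarefy:
    def test_row_sums_equal_depth_and_counts_bounded(self, null_base_table):
        out = rarefy(null_base_table, depth=400, seed=1)
        assert (out.depth == 400).all()
        assert (out.counts <= null_base_table.counts).all()

    def test_sample_at_depth_is_unchanged(self, tiny_table):
        out = rarefy(tiny_table, depth=5, seed=0)
        # sampleB is exactly at depth: the whole multiset is taken
        np.testing.assert_array_equal(out.counts[1], tiny_table.counts[1])

    def test_deterministic_given_seed(self, null_base_table):
        a = rarefy(null_base_table, depth=300, seed=7)
        b = rarefy(null_base_table, depth=300, seed=7)
        c = rarefy(null_base_table, depth=300, seed=8)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert (c.depth == 300).all()
        assert not np.array_equal(a.counts, c.counts)

    def test_shallow_samples_listed_in_error(self, tiny_table):
        with pytest.raises(TableError, match="sampleB"):
            rarefy(tiny_table, depth=8, seed=0)


class TestRelativeAbundance:
    def test_hand_values(self):
        t = CommunityTable(np.array([[6, 2, 0]]), ["s"], ["a", "b", "c"])
        rel = relative_abundance(t)
        np.testing.assert_allclose(rel.to_numpy()[0], [0.75, 0.25, 0.0])

    def test_rows_sum_to_one(self, null_base_table):
        rel = relative_abundance(null_base_table)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_depth_sample_rejected(self):
        t = CommunityTable(np.array([[1, 0], [0, 0]]), ["s1", "s2"], ["a", "b"])
        with pytest.raises(TableError, match="s2"):
            relative_abundance(t)


class TestAridity:
    def test_arithmetic_and_boundary(self):
        assert derive_aridity(100, 1000) == pytest.approx(0.9)
        assert derive_aridity(500, 500) == pytest.approx(0.0)

    def test_nonpositive_pet_rejected(self):
        with pytest.raises(ValueError):
            derive_aridity(100, 0)

    def test_survey_ai_range_accepted(self):
        # arid-region AI of 0.03-0.32 maps to aridity 0.68-0.97
        ai = np.array([0.03, 0.32])
        out = derive_aridity(ai * 1500.0, np.full(2, 1500.0))
        np.testing.assert_allclose(out, 1 - ai)


class TestCollinearityPrune:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        res = collinearity_prune(df, threshold=0.6)
        assert sorted(res.retained + res.dropped) == ["a", "b", "c"]
        assert len(res.dropped) == 1 and res.dropped[0] in ("a", "b")

    def test_uncorrelated_columns_untouched(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        # orthogonalize columns so sample correlations are ~0
        q, _ = np.linalg.qr(X - X.mean(axis=0))
        df = pd.DataFrame(q, columns=list("abcd"))
        res = collinearity_prune(df, threshold=0.6)
        assert res.dropped == []

    def test_output_has_no_violating_pair(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        df = pd.DataFrame({
            f"v{i}": base * w + rng.normal(size=50) * (1 - w)
            for i, w in enumerate([0.95, 0.9, 0.5, 0.2, 0.05])
        })
        res = collinearity_prune(df, threshold=0.6)
        corr = df[res.retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.6

    def test_keep_list_respected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        df = pd.DataFrame({"keepme": x, "b": x + 1e-9 * rng.normal(size=30)})
        res = collinearity_prune(df, threshold=0.6, keep=["keepme"])
        assert "keepme" in res.retained

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            collinearity_prune(df)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
       st.integers(min_value=0, max_value=10))
def test_rarefy_never_exceeds_original_counts(row, depth):
    counts = np.array([row])
    if counts.sum() < depth:
        return
    t = CommunityTable(counts, ["s"], [f"t{i}" for i in range(len(row))])
    out = rarefy(t, depth=depth, seed=0)
    assert out.depth[0] == depth
    assert (out.counts <= t.counts).all()
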