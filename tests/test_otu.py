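"""OTU table reading, validation and normalization transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protistnet import (
    OtuTable,
    OtuTableError,
    filter_min_total,
    hellinger_transform,
    pool_by_habitat,
    pool_replicates,
    rarefy,
    read_otu_table,
    remove_singletons,
    resolve_depth,
)
from protistnet.otu import rarefy_vector


class TestReadOtuTable:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\ts2\no1\t3\t4\no2\t0\t1\no3\t5\t5\n")
        t = read_otu_table(p)
        assert t.shape == (3, 2)
        assert t.counts.loc["o1", "s2"] == 4

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\ts1\no1\t3\t4\n")
        with pytest.raises(OtuTableError, match="duplicat"):
            read_otu_table(p)

    def test_negative_cell_names_location(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\ts2\no1\t3\t-4\n")
        with pytest.raises(OtuTableError, match=r"o1.*s2|s2.*o1"):
            read_otu_table(p)

    def test_non_integer_cell_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\no1\t3.5\n")
        with pytest.raises(OtuTableError):
            read_otu_table(p)

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\n")
        with pytest.raises(OtuTableError):
            read_otu_table(p)

    def test_duplicate_otu_rejected(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["o1", "o1"],
                              columns=["s1", "s2"])
        with pytest.raises(OtuTableError, match="duplicated OTU"):
            OtuTable(counts=counts)


class TestPoolReplicates:
    def test_replicate_columns_are_summed(self, toy_table, toy_metadata):
        pooled, meta = pool_replicates(toy_table, toy_metadata)
        assert pooled.shape == (4, 2)
        # (10,3,0,1) + (8,5,2,0)
        assert pooled.counts["StA1_M1"].tolist() == [18, 8, 2, 1]
        assert set(meta["habitat"]) == {"A", "B"}

    def test_total_reads_conserved(self, toy_table, toy_metadata):
        pooled, _ = pool_replicates(toy_table, toy_metadata)
        assert pooled.total_reads() == toy_table.total_reads()

    def test_single_replicate_passes_through(self, toy_table, toy_metadata):
        meta = toy_metadata.copy()
        meta["station"] = ["StA1", "StA2", "StB1", "StB2"]  # groups of one
        pooled, _ = pool_replicates(toy_table, meta)
        assert pooled.shape[1] == 4
        assert pooled.counts["StA1_M1"].tolist() == toy_table.counts["s1"].tolist()

    def test_fifty_six_samples_pool_to_twenty_eight(self):
        from protistnet import SyntheticConfig, generate_dataset

        table, meta, _, _ = generate_dataset(SyntheticConfig(n_otus=40, seed=3))
        assert table.shape[1] == 56
        pooled, _ = pool_replicates(table, meta)
        assert pooled.shape[1] == 28


class TestRemoveSingletons:
    def test_singleton_dropped_doubleton_kept(self):
        counts = pd.DataFrame({"s1": [1, 1, 0], "s2": [0, 1, 0]},
                              index=["single", "double", "zero"])
        out = remove_singletons(OtuTable(counts=counts))
        assert out.otu_ids == ["double"]

    def test_all_singletons_gives_empty_table(self):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["a", "b"])
        out = remove_singletons(OtuTable(counts=counts))
        assert out.shape[0] == 0

    def test_idempotent(self, toy_table):
        once = remove_singletons(toy_table)
        twice = remove_singletons(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestRarefy:
    def test_column_sums_equal_depth(self, toy_table):
        out = rarefy(toy_table, depth=7, seed=1)
        assert (out.counts.sum(axis=0) == 7).all()

    def test_depth_equal_to_total_is_identity(self):
        counts = pd.DataFrame({"s1": [5, 3, 2]}, index=["a", "b", "c"])
        out = rarefy(OtuTable(counts=counts), depth=10, seed=0)
        assert out.counts["s1"].tolist() == [5, 3, 2]

    def test_rarefied_never_exceeds_original(self, toy_table):
        out = rarefy(toy_table, depth=7, seed=2)
        assert (out.counts.to_numpy() <= toy_table.counts[out.sample_ids].to_numpy()).all()

    def test_below_depth_columns_dropped_with_warning(self, toy_table, caplog):
        out = rarefy(toy_table, depth=10, seed=0)  # s4 has 9 reads
        assert "s4" not in out.sample_ids
        assert out.shape[1] == 3

    def test_seeds_change_draw_not_sums(self):
        counts = pd.DataFrame({"s1": np.arange(1, 21)},
                              index=[f"o{i}" for i in range(20)])
        t = OtuTable(counts=counts)
        a = rarefy(t, depth=100, seed=1).counts
        b = rarefy(t, depth=100, seed=2).counts
        assert a.sum().iloc[0] == b.sum().iloc[0] == 100
        assert not a.equals(b)

    def test_nonpositive_depth_rejected(self, toy_table):
        with pytest.raises(OtuTableError):
            rarefy(toy_table, depth=0, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean subsampled count matches the hypergeometric expectation
        n_i * d / N within 3 Monte-Carlo SE (column (8000, 2000), d=1000)."""
        col = np.array([8000, 2000])
        draws = np.array([
            rarefy_vector(col, 1000, np.random.default_rng(s))[0]
            for s in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 800.0) < 3 * se + 1e-9

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reproducible_under_fixed_seed(self, seed):
        counts = pd.DataFrame({"s1": [40, 30, 20, 10]}, index=list("abcd"))
        t = OtuTable(counts=counts)
        a = rarefy(t, depth=50, seed=seed).counts
        b = rarefy(t, depth=50, seed=seed).counts
        pd.testing.assert_frame_equal(a, b)


class TestResolveDepth:
    def test_policies(self, toy_table):
        # column totals: s1=14, s2=15, s3=11, s4=9
        assert resolve_depth(toy_table, "lowest") == 9
        assert resolve_depth(toy_table, "second-lowest") == 11
        assert resolve_depth(toy_table, 123) == 123


class TestFilterMinTotal:
    @pytest.mark.parametrize("total,kept", [(49, False), (50, True), (51, True)])
    def test_boundary_less_than_excluded(self, total, kept):
        counts = pd.DataFrame({"s1": [total, 100]}, index=["x", "y"])
        out = filter_min_total(OtuTable(counts=counts), 50)
        assert ("x" in out.otu_ids) is kept

    def test_min_one_keeps_everything_positive(self, toy_table):
        out = filter_min_total(toy_table, 1)
        assert out.otu_ids == toy_table.otu_ids


class TestPoolByHabitat:
    def test_pools_normalized_to_smaller_total(self, toy_table, toy_metadata):
        pools = pool_by_habitat(toy_table, toy_metadata, seed=0)
        totals = pools.sum(axis=0)
        assert totals["A"] == totals["B"] == min(29, 20)

    def test_equal_totals_identity(self):
        counts = pd.DataFrame({"s1": [6, 4], "s2": [3, 7]}, index=["a", "b"])
        meta = pd.DataFrame({
            "sample_id": ["s1", "s2"], "station": ["x", "y"],
            "habitat": ["A", "B"], "date": ["M1", "M1"], "replicate": ["1", "1"]})
        pools = pool_by_habitat(OtuTable(counts=counts), meta, seed=0)
        assert pools["A"].tolist() == [6, 4]
        assert pools["B"].tolist() == [3, 7]

    def test_otu_absent_everywhere_retained_as_zero(self, toy_table, toy_metadata):
        pools = pool_by_habitat(toy_table, toy_metadata, seed=0)
        assert "o4" in pools.index  # nearly absent OTU still present

    def test_station_subset_with_empty_habitat_errors(self, toy_table, toy_metadata):
        with pytest.raises(OtuTableError):
            pool_by_habitat(toy_table, toy_metadata, stations=["StA1"])


class TestHellinger:
    def test_uniform_column(self):
        counts = pd.DataFrame({"s1": [1, 1, 1, 1]}, index=list("abcd"))
        out = hellinger_transform(OtuTable(counts=counts))
        assert np.allclose(out["s1"], 0.5)

    def test_concentrated_column(self):
        counts = pd.DataFrame({"s1": [4, 0]}, index=["a", "b"])
        out = hellinger_transform(OtuTable(counts=counts))
        assert out["s1"].tolist() == [1.0, 0.0]

    def test_unit_squared_norm(self, toy_table, rng):
        out = hellinger_transform(toy_table)
        assert np.allclose((out ** 2).sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(OtuTableError, match="s2"):
            hellinger_transform(OtuTable(counts=counts))
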