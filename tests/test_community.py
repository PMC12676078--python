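"""Rarefaction, alpha diversity, distances, dispersion, subsetting."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizoadapt import community as com, synthetic as syn
from rhizoadapt.datatypes import FeatureTable, ValidationError
from .conftest import euclidean_dm


def ft(rows, ids=None, taxa=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return FeatureTable(pd.DataFrame(rows, index=ids, columns=taxa))


class TestRarefy:
    def test_shallow_sample_dropped_and_reported(self):
        table = ft([[50, 50], [100, 100]])
        with pytest.warns(UserWarning, match="s0"):
            out, dropped = com.rarefy(table, 150, seed=0, return_dropped=True)
        assert dropped == ["s0"]
        assert out.sample_ids == ["s1"]

    def test_depth_equal_to_row_sum_is_identity(self):
        table = ft([[60, 40]])
        out = com.rarefy(table, 100, seed=0)
        assert out.data.iloc[0].tolist() == [60, 40]

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), depth=st.integers(1, 80))
    def test_subsample_bounded_and_exact_depth(self, seed, depth):
        rng = np.random.default_rng(seed)
        table = ft(rng.integers(0, 40, size=(4, 6)))
        out = com.rarefy(table, depth, seed=seed)
        sub = out.data.reindex(index=out.sample_ids)
        orig = table.data.loc[out.sample_ids]
        assert (sub.to_numpy() <= orig.to_numpy()).all()
        assert (sub.sum(axis=1) == depth).all()

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            com.rarefy(ft([[1, 2]]), 0, seed=0)


class TestAlpha:
    def test_uniform_counts_have_even_pielou(self):
        out = com.alpha_metrics(ft([[10, 10, 10, 10]]))
        assert out.richness[0] == 4
        assert out.pielou[0] == pytest.approx(1.0)

    def test_single_taxon_sample_flags_pielou_undefined(self):
        out = com.alpha_metrics(ft([[100, 0, 0]]))
        assert out.richness[0] == 1
        assert out.shannon[0] == pytest.approx(0.0)
        assert np.isnan(out.pielou[0])

    def test_shannon_matches_direct_summation(self):
        out = com.alpha_metrics(ft([[1, 2, 3]]))
        p = np.array([1, 2, 3]) / 6
        assert out.shannon[0] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)

    def test_all_zero_sample(self):
        out = com.alpha_metrics(ft([[0, 0]]))
        assert out.richness[0] == 0
        assert np.isnan(out.shannon[0]) and np.isnan(out.pielou[0])


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        dm = com.bray_curtis(ft([[3, 1, 0], [3, 1, 0], [0, 0, 7]]))
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        dm = com.bray_curtis(ft([[6, 0, 2], [2, 2, 0]]))
        assert dm.values[0, 1] == pytest.approx(8 / 12)


class TestWeightedUnifrac:
    def test_path_length_hand_example(self, tmp_path):
        from rhizoadapt import io

        nwk = tmp_path / "t.nwk"
        nwk.write_text("((A:1,B:1):1,C:2);\n")
        tree = io.read_tree(nwk)
        table = ft([[10, 0, 0], [0, 0, 10]], taxa=["A", "B", "C"])
        dm = com.weighted_unifrac(table, tree)
        assert dm.values[0, 1] == pytest.approx(4.0, abs=1e-12)
        assert com.weighted_unifrac(table, tree, normalized=True).values[0, 1] \
            == pytest.approx(1.0)

    def test_identical_samples_distance_zero(self, tmp_path):
        from rhizoadapt import io

        nwk = tmp_path / "t.nwk"
        nwk.write_text("((A:1,B:1):1,C:2);\n")
        tree = io.read_tree(nwk)
        dm = com.weighted_unifrac(ft([[4, 2, 1], [4, 2, 1]], taxa=["A", "B", "C"]), tree)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_taxon_is_an_error_not_a_prune(self, tmp_path):
        from rhizoadapt import io

        nwk = tmp_path / "t.nwk"
        nwk.write_text("((A:1,B:1):1,C:2);\n")
        tree = io.read_tree(nwk)
        table = ft([[1, 1], [1, 1]], taxa=["A", "Z"])
        with pytest.raises(ValidationError, match="Z"):
            com.weighted_unifrac(table, tree)

    def test_star_tree_equals_l1_on_proportions(self):
        # unit-branch star: raw weighted UniFrac == sum |p_i - q_i| exactly
        import skbio
        from rhizoadapt.datatypes import PhyloTree

        taxa = ["A", "B", "C", "D"]
        # zero-length internal edges make this equivalent to a unit star
        star = skbio.TreeNode.read(["((A:1,B:1):0,(C:1,D:1):0);"])
        tree = PhyloTree(star)
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 4))
        dm = com.weighted_unifrac(ft(counts, taxa=taxa), tree)
        P = counts / counts.sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(4), 2):
            assert dm.values[i, j] == pytest.approx(
                np.abs(P[i] - P[j]).sum(), abs=1e-12
            )

    def test_metric_axioms_on_random_small_instances(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(6)]
        tree = syn.gen_tree(taxa, seed=3)
        counts = rng.integers(1, 30, size=(5, 6))
        dm = com.weighted_unifrac(ft(counts, taxa=taxa), tree)
        d = dm.values
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestBetaDispersion:
    def test_euclidean_matches_direct_geometry(self, rng):
        pts = rng.normal(size=(12, 2))
        ids = [f"s{i}" for i in range(12)]
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
        res = com.beta_dispersion(euclidean_dm(pts, ids), groups)
        direct = {}
        for g, sel in (("a", slice(0, 6)), ("b", slice(6, 12))):
            c = pts[sel].mean(axis=0)
            for i in range(*sel.indices(12)):
                direct[ids[i]] = np.linalg.norm(pts[i] - c)
        got = res.distances.set_index("sample_id")["dist_to_centroid"]
        for sid, val in direct.items():
            assert got[sid] == pytest.approx(val, abs=1e-8)

    def test_identical_members_have_zero_dispersion(self):
        pts = np.tile([[1.0, 2.0]], (4, 1))
        ids = [f"s{i}" for i in range(4)]
        res = com.beta_dispersion(euclidean_dm(pts, ids),
                                  pd.Series(["g"] * 4, index=ids))
        assert np.allclose(res.distances["dist_to_centroid"], 0.0, atol=1e-8)

    def test_doubling_distances_doubles_dispersion(self, rng):
        pts = rng.normal(size=(9, 3))
        ids = [f"s{i}" for i in range(9)]
        groups = pd.Series(["a", "b", "c"] * 3, index=ids)
        dm1 = euclidean_dm(pts, ids)
        dm2 = euclidean_dm(2 * pts, ids)
        r1 = com.beta_dispersion(dm1, groups).distances["dist_to_centroid"]
        r2 = com.beta_dispersion(dm2, groups).distances["dist_to_centroid"]
        assert np.allclose(r2, 2 * r1, atol=1e-8)

    def test_singleton_group_skipped_with_warning(self, rng):
        pts = rng.normal(size=(5, 2))
        ids = [f"s{i}" for i in range(5)]
        groups = pd.Series(["a", "a", "a", "a", "lone"], index=ids)
        with pytest.warns(UserWarning, match="lone"):
            res = com.beta_dispersion(euclidean_dm(pts, ids), groups)
        assert res.skipped_groups == ["lone"]


class TestSubsetAndAggregate:
    def test_relative_abundance_uses_parent_totals(self, taxonomy80):
        counts = np.zeros((1, 80), dtype=int)
        flagged = sorted(taxonomy80.flagged("ammonia_oxidizer"))
        taxa = taxonomy80.taxon_ids
        counts[0, taxa.index(flagged[0])] = 10
        counts[0, 0 if taxa[0] not in flagged else 1] = 990
        table = FeatureTable(pd.DataFrame(counts, index=["s"], columns=taxa))
        sub, ra = com.subset_functional_group(table, taxonomy80, "ammonia_oxidizer")
        assert ra["s"] == pytest.approx(0.01)
        assert set(sub.taxon_ids) <= set(flagged)

    def test_flag_partition_reconstitutes_parent(self, small_community, taxonomy80):
        table, _ = small_community
        sub, _ = com.subset_functional_group(table, taxonomy80, "ammonia_oxidizer")
        rest = [t for t in table.taxon_ids if t not in set(sub.taxon_ids)]
        total = sub.data.sum(axis=1) + table.data[rest].sum(axis=1)
        assert (total == table.row_sums()).all()

    def test_aggregate_conserves_totals_and_merges(self, small_community, taxonomy80):
        table, _ = small_community
        merged = com.aggregate_to_rank(table, taxonomy80, "order")
        assert (merged.row_sums() == table.row_sums()).all()
        assert merged.shape[1] < table.shape[1]

    def test_two_asvs_same_order_merge_counts(self):
        from rhizoadapt.datatypes import TaxonomyTable

        ranks = pd.DataFrame({"order": ["o1", "o1", "o2"]},
                             index=pd.Index(["a", "b", "c"], name="taxon_id"))
        tax = TaxonomyTable(ranks=ranks)
        merged = com.aggregate_to_rank(ft([[3, 4, 5]], taxa=["a", "b", "c"]), tax, "order")
        assert merged.data.loc["s0", "o1"] == 7

    def test_asv_level_aggregation_is_identity(self, small_community, taxonomy80):
        table, _ = small_community
        out = com.aggregate_to_rank(table, taxonomy80, "asv")
        assert out == table

    def test_aggregation_never_increases_richness(self, small_community, taxonomy80):
        table, _ = small_community
        before = com.alpha_metrics(table)["richness"]
        after = com.alpha_metrics(com.aggregate_to_rank(table, taxonomy80, "genus"))["richness"]
        assert (after.to_numpy() <= before.to_numpy()).all()
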