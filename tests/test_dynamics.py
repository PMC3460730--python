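import numpy as np
import pandas as pd
import pytest

from hicseg import dynamics as dyn
from hicseg.hic_io import BinGrid, GeneTable
from hicseg.mcl_clustering import Cluster, ClusterSet, label_boundaries
from hicseg.segmentation import RatioTrack, assign_states


def make_clusters(groups, chrom="chr1", start_cid=0):
    cs = ClusterSet(
        [Cluster(start_cid + i, chrom, np.array(sorted(g))) for i, g in enumerate(groups)],
        inflation=3.0,
    )
    return label_boundaries(cs)


def make_states(R, chrom="chr1"):
    grid = BinGrid({chrom: len(R) * 100_000})
    track, _ = assign_states(RatioTrack(chrom, np.asarray(R, float), d=1), None, grid)
    return {chrom: track}


def genes_at_bins(bins, chrom="chr1"):
    rows = [
        {"gene": f"g{i}", "chrom": chrom, "tss": b * 100_000 + 500, "strand": "+",
         "expression": 1.0}
        for i, b in enumerate(bins)
    ]
    return GeneTable(pd.DataFrame(rows))


class TestPercentileGroups:
    def test_identical_tracks_all_common(self):
        p = {"chr1": np.array([5.0, 50.0, 95.0, np.nan])}
        common, a_only, b_only = dyn.percentile_group_bins(p, p, 90, 100)
        assert common == {("chr1", 2)} and not a_only and not b_only

    def test_disjoint_top_ranks_all_specific(self):
        pa = {"chr1": np.linspace(10, 100, 10)}
        pb = {"chr1": np.linspace(100, 10, 10)}
        common, a_only, b_only = dyn.percentile_group_bins(pa, pb, 90, 100)
        assert common == set()
        assert a_only == {("chr1", 9)} and b_only == {("chr1", 0)}

    def test_specific_bins_bookkeeping(self):
        pa = np.full(10, 50.0); pa[7] = 95.0
        pb = np.full(10, 50.0); pb[3] = 95.0
        common, a_only, b_only = dyn.percentile_group_bins({"chr1": pa}, {"chr1": pb}, 90, 100)
        assert a_only == {("chr1", 7)} and b_only == {("chr1", 3)} and not common

    def test_partition_identity(self):
        rng = np.random.default_rng(0)
        pa = {"chr1": rng.uniform(0, 100, 50)}
        pb = {"chr1": rng.uniform(0, 100, 50)}
        common, a_only, _ = dyn.percentile_group_bins(pa, pb, 60, 70)
        in_range_a = {("chr1", int(i)) for i in np.flatnonzero((pa["chr1"] > 60) & (pa["chr1"] <= 70))}
        assert common | a_only == in_range_a and not common & a_only

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            dyn.percentile_group_bins({}, {}, 50, 50)


class TestGeneSetScore:
    def test_exact_binomial_score(self):
        # n=20 genes, bin set covers 25% of bins, k=10 hits -> p ~ 0.01386
        grid = BinGrid({"chr1": 40 * 100_000})
        bins = {("chr1", i) for i in range(10)}
        genes = genes_at_bins(list(range(10)) + list(range(20, 30)))
        score = dyn.gene_set_enrichment_score(bins, genes, all_bins=40, grid=grid)
        assert score == pytest.approx(1.858, abs=0.01)

    def test_expected_hit_rate_scores_low(self):
        grid = BinGrid({"chr1": 40 * 100_000})
        bins = {("chr1", i) for i in range(10)}  # p0 = 0.25
        genes = genes_at_bins([1, 2, 3, 4, 5] + list(range(20, 35)))  # k=5 of n=20
        score = dyn.gene_set_enrichment_score(bins, genes, all_bins=40, grid=grid)
        assert score < 0.7

    def test_extreme_concentration_scores_high(self):
        grid = BinGrid({"chr1": 100 * 100_000})
        bins = {("chr1", i) for i in range(10)}  # 10% of bins
        genes = genes_at_bins(list(np.arange(575) % 10))
        score = dyn.gene_set_enrichment_score(bins, genes, all_bins=100, grid=grid)
        assert score > 100

    def test_empty_gene_set_rejected(self):
        grid = BinGrid({"chr1": 10 * 100_000})
        with pytest.raises(ValueError):
            dyn.gene_set_enrichment_score({("chr1", 1)}, genes_at_bins([]), 10, grid)


class TestPairDynamics:
    def test_identical_conditions_diagonal(self):
        states = make_states([1, 1, 1, 1, 1, 1, -1, 1, 1])
        cs = make_clusters([[0, 1, 2], [3, 4, 5], [7, 8]])
        table = dyn.pair_dynamics(states, cs, states, cs)
        assert table.loc["Same", "Same"] == 1.0
        assert table.loc["Diff", "Diff"] == 1.0

    def test_all_minus_b_goes_to_minus_column(self):
        states_a = make_states([1, 1, 1, 1])
        cs_a = make_clusters([[0, 1], [2, 3]])
        states_b = make_states([-1, -1, -1, -1])
        table = dyn.pair_dynamics(states_a, cs_a, states_b, make_clusters([]))
        assert table.loc["Same", "Minus"] == 1.0
        assert table.loc["Diff", "Minus"] == 1.0

    def test_counted_fractions(self):
        # 4 Diff pairs in A -> 1 Diff, 2 Same, 1 Minus in B
        states_a = make_states([1, 1, 1, 1, 1, -1, 1, 1, -1])
        cs_a = make_clusters([[0], [1], [2], [3, 4], [6], [7]])
        states_b = make_states([1, 1, 1, 1, 1, -1, 1, -1, -1])
        cs_b = make_clusters([[0, 1, 2], [3], [4], [6]])
        table = dyn.pair_dynamics(states_a, cs_a, states_b, cs_b)
        # Diff pairs in A: (0,1) (1,2) (2,3) (6,7); in B: Same, Same, Diff, Minus
        assert table.loc["Diff"].tolist() == pytest.approx([0.5, 0.25, 0.25])

    def test_rows_sum_to_one(self, default_pipeline):
        plan = default_pipeline["plan"]
        states = {plan.chrom: default_pipeline["track"]}
        cs = default_pipeline["clusters"]
        table = dyn.pair_dynamics(states, cs, states, cs)
        np.testing.assert_allclose(table.sum(axis=1), 1.0)

    def test_no_clustered_pairs_rejected(self):
        states = make_states([-1, -1])
        with pytest.raises(ValueError):
            dyn.pair_dynamics(states, make_clusters([]), states, make_clusters([]))


class TestBoundaryClasses:
    def test_identical_all_common(self):
        cs = make_clusters([[0, 1, 2, 3]])
        out = dyn.classify_boundaries(cs, cs)
        assert set(out["class"]) == {"common"}

    def test_empty_b_all_specific(self):
        cs = make_clusters([[0, 1, 2, 3]])
        out = dyn.classify_boundaries(cs, make_clusters([]))
        assert set(out["class"]) == {"A_specific"}

    def test_set_intersection_semantics(self):
        cs_a = make_clusters([[3, 4, 5], [9, 10, 11]])     # boundaries {3,5,9,11}
        cs_b = make_clusters([[9, 10, 11], [14, 15, 16]])  # boundaries {9,11,14,16}
        out = dyn.classify_boundaries(cs_a, cs_b)
        common = set(out[out["class"] == "common"]["bin"])
        assert common == {9, 11}
        assert len(out) == 4  # counts partition all A boundary bins


class TestJaccard:
    def test_identical_clusters_one(self):
        cs = make_clusters([[1, 2, 3]])
        assert dyn.cluster_jaccard("chr1", 2, cs, cs) == 1.0

    def test_set_arithmetic(self):
        a = make_clusters([[1, 2, 3]])
        b = make_clusters([[2, 3, 4]])
        assert dyn.cluster_jaccard("chr1", 2, a, b) == pytest.approx(0.5)

    def test_single_shared_bin(self):
        a = make_clusters([[5, 6, 7, 8, 9]])
        b = make_clusters([[1, 2, 3, 4, 5]])
        assert dyn.cluster_jaccard("chr1", 5, a, b) == pytest.approx(1 / 9)

    def test_symmetry(self):
        a = make_clusters([[1, 2, 3, 4]])
        b = make_clusters([[3, 4, 5]])
        assert dyn.cluster_jaccard("chr1", 3, a, b) == dyn.cluster_jaccard("chr1", 3, b, a)

    def test_unclustered_bin_rejected(self):
        a = make_clusters([[1, 2, 3]])
        with pytest.raises(ValueError):
            dyn.cluster_jaccard("chr1", 7, a, a)


class TestDeAssociation:
    def test_rearranged_bins_have_smaller_jaccard(self):
        a = make_clusters([[0, 1, 2, 3], [4, 5, 6, 7]])
        # b keeps the first cluster, shreds the second
        b_cs = make_clusters([[0, 1, 2, 3], [4, 5], [6, 7]])
        de = {("chr1", i): (1.0 if i >= 4 else 0.0) for i in range(8)}
        out = dyn.de_association(de, a, b_cs, top_frac=0.5, bottom_frac=0.5)
        assert out["mean_jaccard_top"] < out["mean_jaccard_bottom"]

    def test_degenerate_single_bin_tiers(self):
        a = make_clusters([[0, 1, 2, 3]])
        de = {("chr1", 0): 0.9, ("chr1", 3): 0.1}
        out = dyn.de_association(de, a, a, top_frac=0.01, bottom_frac=0.01)
        assert out["n_top"] == 1 and out["mean_jaccard_top"] == 1.0

    def test_too_few_bins_rejected(self):
        a = make_clusters([[0, 1, 2]])
        with pytest.raises(ValueError):
            dyn.de_association({("chr1", 0): 0.5}, a, a)
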