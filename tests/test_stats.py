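import itertools

import numpy as np
import pandas as pd
import pytest

from hicseg.hic_io import BinGrid, ContactMap, GeneTable, IntervalSet
from hicseg.mcl_clustering import Cluster, ClusterSet, label_boundaries
from hicseg.stats import (
    adjust_pvalues,
    boundary_enrichment,
    expression_tier_enrichment,
    sample_replicate_map,
    simulate_null,
    within_across_fold,
)


def make_clusters(groups, chrom="chr1", inflation=3.0):
    cs = ClusterSet(
        [Cluster(i, chrom, np.array(sorted(g))) for i, g in enumerate(groups)], inflation
    )
    return label_boundaries(cs)


def exact_ranksum_p(x, y):
    """One-sided rank-sum p-value by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:nx].sum()
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    return np.mean([s >= obs for s in stats])


class TestWithinAcrossFold:
    def test_ratio_of_means(self):
        # two clusters of 2 bins; within pairs count 4, across pairs count 2
        cm = ContactMap.from_arrays(
            "chr1", 10,
            [0, 5, 0, 0, 1, 1], [1, 6, 5, 6, 5, 6],
            [4, 4, 2, 2, 2, 2],
        )
        cs = make_clusters([[0, 1], [5, 6]])
        fold, _ = within_across_fold({"chr1": cm}, cs)
        assert fold == pytest.approx(2.0)

    def test_toy_fold_and_exact_ranksum(self):
        # within per-pair counts (3, 5); across (1, 3, 1, 3) -> fold 4/2 = 2.0
        cm = ContactMap.from_arrays(
            "chr1", 8,
            [0, 4, 0, 0, 1, 1], [1, 5, 4, 5, 4, 5],
            [3, 5, 1, 3, 1, 3],
        )
        cs = make_clusters([[0, 1], [4, 5]])
        fold, p = within_across_fold({"chr1": cm}, cs)
        assert fold == pytest.approx(2.0)
        assert p == pytest.approx(exact_ranksum_p([3, 5], [1, 3, 1, 3]), abs=0.02)

    def test_identical_distributions_give_fold_one(self):
        rng = np.random.default_rng(0)
        lc = 40
        m, n = np.triu_indices(lc, k=1)
        cm = ContactMap.from_arrays("chr1", lc, m, n, rng.poisson(10, size=len(m)) + 1)
        cs = make_clusters([list(range(0, 20)), list(range(20, 40))])
        fold, p = within_across_fold({"chr1": cm}, cs)
        assert fold == pytest.approx(1.0, abs=0.1)
        assert p > 0.01

    def test_requires_across_pairs(self):
        cm = ContactMap.from_arrays("chr1", 4, [0], [1], [5])
        with pytest.raises(ValueError):
            within_across_fold({"chr1": cm}, make_clusters([[0, 1]]))


class TestSimulateNull:
    def test_replicates_conserve_per_distance_totals(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 30, 200)
        n = rng.integers(0, 30, 200)
        cm = ContactMap.from_arrays("chr1", 30, m, n, rng.integers(1, 20, 200))
        for rep_seed in range(3):
            rep = sample_replicate_map(cm, np.random.default_rng(rep_seed))
            np.testing.assert_array_equal(rep.distance_totals(), cm.distance_totals())

    def test_same_seed_reproduces_ensemble(self):
        cm = ContactMap.from_dense("chr1", np.full((12, 12), 3.0))
        cs = make_clusters([[0, 1, 2, 3], [6, 7, 8, 9]])
        a = simulate_null({"chr1": cm}, cs, n_reps=5, seed=3)
        b = simulate_null({"chr1": cm}, cs, n_reps=5, seed=3)
        np.testing.assert_array_equal(a.folds, b.folds)

    def test_planted_structure_beats_null(self, default_pipeline):
        plan = default_pipeline["plan"]
        ens = simulate_null(
            {plan.chrom: default_pipeline["filtered"]},
            default_pipeline["clusters"],
            n_reps=50,
            seed=4,
        )
        assert ens.observed_fold > np.quantile(ens.folds, 0.975)


class TestBoundaryEnrichment:
    def _grid(self, lc=60):
        return BinGrid({"chr1": lc * 100_000})

    def _features_at_bins(self, bins):
        rows = [{"chrom": "chr1", "start": b * 100_000 + 10, "end": b * 100_000 + 20,
                 "name": f"p{i}"} for i, b in enumerate(bins)]
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))

    def test_density_ratio_fold(self):
        # clusters with 10 boundary + 30 interior bins total
        cs = make_clusters([list(range(i * 12, i * 12 + 8)) for i in range(5)])
        boundary = sorted(b for _, b in cs.boundary_bins(eligible_only=True))
        interior = sorted(b for _, b in cs.interior_bins())
        feats = self._features_at_bins(boundary * 2 + interior)  # 20 boundary, 30 interior
        res = boundary_enrichment(feats, cs, self._grid(), name="toy")
        assert res.fold == pytest.approx((20 / 10) / (30 / 30))

    def test_exact_binomial_tail_56_over_1024(self):
        # equal boundary/interior bin counts (p0 = 1/2); k=8 of 10 features on
        # boundaries -> one-sided tail P(X >= 8) = 56/1024
        cs = make_clusters([[0, 1, 2, 3], [10, 11, 12, 13]])
        assert len(cs.boundary_bins(eligible_only=True)) == 4
        assert len(cs.interior_bins()) == 4
        feats = self._features_at_bins([0, 0, 3, 3, 10, 10, 13, 13, 1, 11])
        res = boundary_enrichment(feats, cs, self._grid(), name="toy")
        assert res.k_boundary == 8 and res.k_interior == 2
        assert res.p_value == pytest.approx(56 / 1024)

    def test_uniform_features_fold_near_one(self):
        rng = np.random.default_rng(8)
        cs = make_clusters([list(range(i * 10, i * 10 + 10)) for i in range(6)])
        bins = [b for _, b in sorted(cs.boundary_bins(eligible_only=True) | cs.interior_bins())]
        feats = self._features_at_bins(rng.choice(bins, size=2000))
        res = boundary_enrichment(feats, cs, self._grid(), name="uniform")
        assert res.fold == pytest.approx(1.0, abs=0.15)

    def test_no_interior_features_infinite_fold(self):
        cs = make_clusters([list(range(0, 8))])
        feats = self._features_at_bins([0, 7])
        res = boundary_enrichment(feats, cs, self._grid(), name="edge")
        assert np.isinf(res.fold) and 0 <= res.p_value <= 1

    def test_requires_eligible_clusters(self):
        cs = make_clusters([[3, 4]])  # no interior bin anywhere
        with pytest.raises(ValueError, match="eligible"):
            boundary_enrichment(self._features_at_bins([3]), cs, self._grid())


class TestExpressionTiers:
    def _genes(self, bins, exprs):
        rows = [{"gene": f"g{i}", "chrom": "chr1", "tss": b * 100_000 + 50,
                 "strand": "+", "expression": e} for i, (b, e) in enumerate(zip(bins, exprs))]
        return GeneTable(pd.DataFrame(rows))

    def test_quartile_split_sizes(self):
        cs = make_clusters([list(range(0, 8))])
        genes = self._genes([1, 2, 3, 4, 5, 6, 1, 2], list(range(1, 9)))
        res = expression_tier_enrichment(genes, cs, BinGrid({"chr1": 10 * 100_000}))
        by_name = {r.feature: r for r in res}
        top = by_name["expr_top25"]
        assert top.k_boundary + top.k_interior == 2  # genes with values {7, 8}

    def test_boundary_biased_top_tier_has_highest_fold(self):
        cs = make_clusters([list(range(0, 10))])  # boundary {0, 9}
        bins = [0, 9, 0, 9] + [3, 4, 5, 6, 2, 3, 4, 5] + [2, 3, 4, 5]
        exprs = [16, 15, 14, 13] + [8, 7, 6, 5, 4, 3, 12, 11] + [2, 1.5, 1, 0.5]
        res = expression_tier_enrichment(self._genes(bins, exprs), cs,
                                         BinGrid({"chr1": 10 * 100_000}))
        folds = {r.feature: r.fold for r in res}
        assert folds["expr_top25"] > folds["expr_middle50"]
        assert folds["expr_top25"] > folds["expr_bottom25"]

    def test_constant_expression_rejected(self):
        cs = make_clusters([list(range(0, 8))])
        genes = self._genes([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="equal"):
            expression_tier_enrichment(genes, cs, BinGrid({"chr1": 10 * 100_000}))


class TestAdjustPvalues:
    def _results(self, ps):
        from hicseg.stats import EnrichmentResult

        return [EnrichmentResult(f"f{i}", 1.0, p, None, 0, 0, 1, 1) for i, p in enumerate(ps)]

    def test_single_test_unchanged(self):
        out = adjust_pvalues(self._results([0.04]))
        assert out[0].adjusted_p == pytest.approx(0.04)

    def test_bh_hand_computed(self):
        out = adjust_pvalues(self._results([0.01, 0.02, 0.03]), method="bh")
        assert [r.adjusted_p for r in out] == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_multiplies(self):
        out = adjust_pvalues(self._results([0.02] + [0.5] * 34), method="bonferroni")
        assert out[0].adjusted_p == pytest.approx(0.7)

    def test_adjusted_never_below_raw(self):
        ps = [0.001, 0.2, 0.04, 0.9]
        out = adjust_pvalues(self._results(ps))
        assert all(r.adjusted_p >= r.p_value for r in out)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(self._results([1.5]))
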