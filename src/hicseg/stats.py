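"""Validation statistics for the inferred clusters.

Two families of checks:

* structural — per-pair contact counts inside clusters versus across
  clusters (ratio of means, one-sided rank-sum test), with a
  distance-preserving simulated null: each replicate redistributes exactly
  the observed number of contacts at every bin distance uniformly over the
  bin pairs at that distance, so the distance-decay profile is conserved and
  only the positional structure is destroyed;

* functional — enrichment of peaks / TSSs / expression tiers in cluster
  boundary bins against interior bins of eligible clusters (one-sided
  binomial tail on the boundary/interior split), with multiple-testing
  adjustment across a feature panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .hic_io import BinGrid, ContactMap, GeneTable, IntervalSet
from .mcl_clustering import ClusterSet


@dataclass
class EnrichmentResult:
    feature: str
    fold: float
    p_value: float
    adjusted_p: float | None
    k_boundary: int
    k_interior: int
    n_boundary_bins: int
    n_interior_bins: int


@dataclass
class NullEnsemble:
    observed_fold: float
    folds: np.ndarray
    n_reps: int

    def percentile_of_observed(self) -> float:
        """Fraction (in percent) of simulated folds below the observed fold."""
        return 100.0 * float(np.mean(self.folds < self.observed_fold))

    def summary(self) -> dict:
        return {
            "observed_fold": self.observed_fold,
            "mean_simulated_fold": float(np.mean(self.folds)),
            "percentile_of_observed": self.percentile_of_observed(),
            "n_reps": self.n_reps,
        }


def _pair_counts(
    maps: dict[str, ContactMap], clusters: ClusterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair counts for all within-cluster and across-cluster bin pairs.

    Pairs are unordered pairs of clustered bins on the same chromosome;
    pairs with no observed contact contribute a zero.
    """
    within, across = [], []
    by_chrom: dict[str, list] = {}
    for cl in clusters.clusters:
        by_chrom.setdefault(cl.chrom, []).append(cl)
    for chrom, cls in by_chrom.items():
        if chrom not in maps:
            continue
        bins = np.concatenate([cl.bins for cl in cls])
        labels = np.concatenate([np.full(cl.size, cl.cid) for cl in cls])
        order = np.argsort(bins, kind="stable")
        bins, labels = bins[order], labels[order]
        sub = maps[chrom].sym()[bins][:, bins].toarray()
        iu, ju = np.triu_indices(len(bins), k=1)
        same = labels[iu] == labels[ju]
        vals = sub[iu, ju]
        within.append(vals[same])
        across.append(vals[~same])
    w = np.concatenate(within) if within else np.array([])
    a = np.concatenate(across) if across else np.array([])
    return w, a


def within_across_fold(
    maps: dict[str, ContactMap], clusters: ClusterSet
) -> tuple[float, float]:
    """Ratio of mean within-cluster to mean across-cluster per-pair counts.

    The p-value is a one-sided rank-sum test (within > across) on the two
    per-pair count samples: exact enumeration of group assignments for tiny
    samples (total <= 12, where ties would distort the normal approximation),
    the Mann-Whitney normal approximation otherwise.
    """
    w, a = _pair_counts(maps, clusters)
    if len(w) == 0 or len(a) == 0:
        raise ValueError("need at least one within-cluster and one across-cluster pair")
    if a.mean() == 0:
        raise ValueError("across-cluster pairs have zero total count")
    fold = float(w.mean() / a.mean())
    if len(w) + len(a) <= 12:
        def rank_sum(x, y):
            return sps.rankdata(np.concatenate((x, y)))[: len(x)].sum()

        res = sps.permutation_test(
            (w, a), rank_sum, permutation_type="independent",
            alternative="greater", n_resamples=np.inf,
        )
        p = float(res.pvalue)
    else:
        p = float(sps.mannwhitneyu(w, a, alternative="greater").pvalue)
    return fold, p


def _per_distance_totals(cmap: ContactMap) -> np.ndarray:
    return cmap.distance_totals()


def sample_replicate_map(cmap: ContactMap, rng: np.random.Generator) -> ContactMap:
    """One distance-preserving random replicate of a contact map.

    For every bin distance t, the observed total N_t is redistributed by a
    uniform multinomial over the lc - t bin pairs at that distance; the
    replicate therefore conserves each per-distance total exactly.
    """
    lc = cmap.lc
    totals = _per_distance_totals(cmap)
    rows, cols, vals = [], [], []
    for t in np.flatnonzero(totals > 0):
        counts = rng.multinomial(int(totals[t]), np.full(lc - t, 1.0 / (lc - t)))
        nz = np.flatnonzero(counts)
        rows.append(nz)
        cols.append(nz + t)
        vals.append(counts[nz])
    if rows:
        return ContactMap.from_arrays(
            cmap.chrom, lc, np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)
        )
    return ContactMap.from_arrays(cmap.chrom, lc, [], [], [])


def simulate_null(
    maps: dict[str, ContactMap],
    clusters: ClusterSet,
    n_reps: int = 1000,
    seed: int = 0,
) -> NullEnsemble:
    """Distance-preserving null ensemble of within/across fold values.

    Uses the same per-distance multinomial draw as :func:`sample_replicate_map`
    but accumulates only the count mass landing on within- and across-cluster
    pairs, which is all the fold needs.  Deterministic under *seed*.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    # precompute, per chromosome and per distance, which pair offsets are
    # within- vs across-cluster, plus total pair counts for the means
    plans = []
    n_within_pairs = n_across_pairs = 0
    by_chrom: dict[str, list] = {}
    for cl in clusters.clusters:
        by_chrom.setdefault(cl.chrom, []).append(cl)
    for chrom, cls in by_chrom.items():
        if chrom not in maps:
            continue
        cmap = maps[chrom]
        lc = cmap.lc
        label = np.full(lc, -1)
        for cl in cls:
            label[cl.bins] = cl.cid
        totals = _per_distance_totals(cmap)
        per_t = {}
        for t in np.flatnonzero(totals > 0):
            m = np.arange(lc - t)
            both = (label[m] >= 0) & (label[m + t] >= 0)
            same = both & (label[m] == label[m + t])
            diff = both & ~same
            per_t[int(t)] = (int(totals[t]), np.flatnonzero(same), np.flatnonzero(diff))
        clustered = np.flatnonzero(label >= 0)
        iu, ju = np.triu_indices(len(clustered), k=1)
        same_all = label[clustered[iu]] == label[clustered[ju]]
        n_within_pairs += int(same_all.sum())
        n_across_pairs += int((~same_all).sum())
        plans.append((lc, per_t))

    if n_within_pairs == 0 or n_across_pairs == 0:
        raise ValueError("need within- and across-cluster pairs for the null")

    observed_fold, _ = within_across_fold(maps, clusters)
    folds = np.empty(n_reps)
    for r in range(n_reps):
        w_sum = a_sum = 0.0
        for lc, per_t in plans:
            for t, (N_t, same_idx, diff_idx) in per_t.items():
                counts = rng.multinomial(N_t, np.full(lc - t, 1.0 / (lc - t)))
                w_sum += counts[same_idx].sum()
                a_sum += counts[diff_idx].sum()
        folds[r] = (w_sum / n_within_pairs) / max(a_sum / n_across_pairs, 1e-300)
    return NullEnsemble(observed_fold, folds, n_reps)


def _features_to_bins(features, grid: BinGrid) -> set[tuple[str, int]] | list[tuple[str, int]]:
    if isinstance(features, IntervalSet):
        df = features.to_bins(grid)
    elif isinstance(features, GeneTable):
        df = features.tss_bins(grid)
    else:
        return list(features)  # already (chrom, bin) pairs
    return list(zip(df["chrom"], df["bin"]))


def boundary_enrichment(
    features, clusters: ClusterSet, grid: BinGrid, name: str = "feature"
) -> EnrichmentResult:
    """Enrichment of a feature set in cluster boundary bins vs interior bins.

    Only eligible clusters (those with at least one interior bin) contribute
    bins, so every cluster supplies both test and control material.  Peaks
    map to the bin of their midpoint, genes to the bin of their TSS.  The
    p-value is the one-sided binomial tail P(X >= k) with k the boundary
    feature count out of k+m features and success probability the boundary
    share of eligible bins.
    """
    boundary = clusters.boundary_bins(eligible_only=True)
    interior = clusters.interior_bins(eligible_only=True)
    nb, ni = len(boundary), len(interior)
    if nb == 0 or ni == 0:
        raise ValueError("no eligible clusters with boundary and interior bins")
    locs = _features_to_bins(features, grid)
    k = sum(1 for loc in locs if loc in boundary)
    m = sum(1 for loc in locs if loc in interior)
    if m == 0:
        fold = float("inf") if k > 0 else float("nan")
    else:
        fold = (k / nb) / (m / ni)
    p0 = nb / (nb + ni)
    p = float(sps.binom.sf(k - 1, k + m, p0)) if k + m > 0 else 1.0
    return EnrichmentResult(name, fold, p, None, k, m, nb, ni)


def expression_tier_enrichment(
    genes: GeneTable, clusters: ClusterSet, grid: BinGrid
) -> list[EnrichmentResult]:
    """Boundary enrichment of the top 25% / middle 50% / bottom 25% expressed genes.

    Genes are ranked by expression (missing values dropped); each outer tier
    holds round(0.25 n) genes.  Highly expressed genes cluster at boundaries
    in real data, so the expected ordering of folds is top > middle > bottom.
    """
    df = genes.df.dropna(subset=["expression"]).reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("need expression for at least 4 genes")
    if df["expression"].nunique() == 1:
        raise ValueError("all expression values equal; tiers undefined")
    order = np.argsort(df["expression"].to_numpy(), kind="stable")
    q = int(round(0.25 * len(df)))
    tiers = {
        "expr_bottom25": order[:q],
        "expr_middle50": order[q : len(df) - q],
        "expr_top25": order[len(df) - q :],
    }
    out = []
    for name in ("expr_top25", "expr_middle50", "expr_bottom25"):
        sub = GeneTable(df.iloc[tiers[name]].reset_index(drop=True))
        out.append(boundary_enrichment(sub, clusters, grid, name=name))
    return out


def adjust_pvalues(results: list[EnrichmentResult], method: str = "bh") -> list[EnrichmentResult]:
    """Attach adjusted p-values (Benjamini-Hochberg by default, or Bonferroni)."""
    pvals = np.array([r.p_value for r in results])
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    adj = multipletests(pvals, method=sm_method)[1]
    return [replace(r, adjusted_p=float(a)) for r, a in zip(results, adj)]


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "fold": r.fold,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "k_boundary": r.k_boundary,
                "k_interior": r.k_interior,
                "n_boundary_bins": r.n_boundary_bins,
                "n_interior_bins": r.n_interior_bins,
            }
            for r in results
        ]
    )
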