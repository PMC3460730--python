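"""Cross-cell-type dynamics of states and clusters.

Given segmentations and cluster sets from two conditions (cell lines A and B)
on the same bin grid, this module quantifies how stable the inferred
organization is: which high-ratio bins are shared, how adjacent-bin cluster
relationships (Same / Diff / Minus) shift, which cluster boundaries are
condition-common versus condition-specific, and whether bins rich in
differentially expressed genes sit in rearranged clusters (small Jaccard
index between the two clusters containing the bin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hic_io import BinGrid, GeneTable
from .mcl_clustering import ClusterSet
from .segmentation import PLUS, RatioTrack

SAME, DIFF, MINUS_CAT = "Same", "Diff", "Minus"


def percentile_group_bins(
    pct_a: dict[str, np.ndarray],
    pct_b: dict[str, np.ndarray],
    lo: float,
    hi: float,
) -> tuple[set, set, set]:
    """Split bins of a percentile range into common / A-specific / B-specific.

    *pct_a*, *pct_b* are genome-wide percentile tracks (NaN = gap).  A bin is
    in range when lo < pct <= hi (pct == 0 included when lo == 0); common =
    in range in both conditions, specific = in range in exactly one.
    """
    if not (0 <= lo < hi <= 100):
        raise ValueError("need 0 <= lo < hi <= 100")

    def in_range(p):
        with np.errstate(invalid="ignore"):
            sel = (p > lo) & (p <= hi)
            if lo == 0:
                sel |= p == 0
        return sel

    common, a_only, b_only = set(), set(), set()
    for chrom in set(pct_a) | set(pct_b):
        a = in_range(pct_a.get(chrom, np.array([])))
        b = in_range(pct_b.get(chrom, np.array([])))
        n = max(len(a), len(b))
        a = np.pad(a, (0, n - len(a)))
        b = np.pad(b, (0, n - len(b)))
        common.update((chrom, int(i)) for i in np.flatnonzero(a & b))
        a_only.update((chrom, int(i)) for i in np.flatnonzero(a & ~b))
        b_only.update((chrom, int(i)) for i in np.flatnonzero(~a & b))
    return common, a_only, b_only


def gene_set_enrichment_score(
    bins: set, genes: GeneTable, all_bins: int, grid: BinGrid
) -> float:
    """-log10 binomial p-value for genes of a set landing in a bin set.

    k genes of the set (out of n) have their TSS in *bins*; under the null a
    TSS lands in the set with probability |bins| / all_bins (all_bins = the
    number of non-gap bins genome-wide).  Score = -log10 P(X >= k).  Used
    e.g. to show housekeeping genes concentrate in condition-common
    high-ratio bins.
    """
    if len(bins) == 0:
        raise ValueError("empty bin set")
    n = len(genes)
    if n == 0:
        raise ValueError("empty gene set")
    locs = genes.tss_bins(grid)
    k = sum(1 for c, b in zip(locs["chrom"], locs["bin"]) if (c, int(b)) in bins)
    p0 = len(bins) / all_bins
    # logsf keeps precision when the tail underflows
    log_p = sps.binom.logsf(k - 1, n, p0)
    return float(-log_p / np.log(10))


def _pair_category(
    chrom: str, i: int, states: dict[str, RatioTrack], bin2cluster: dict
) -> str:
    """Category of the adjacent pair (i, i+1): Same / Diff / Minus.

    Minus when either bin is minus/gap state or unclustered (an isolated
    plus bin behaves like a non-participant).
    """
    sa = states[chrom].state
    ca, cb = bin2cluster.get((chrom, i)), bin2cluster.get((chrom, i + 1))
    if sa[i] != PLUS or sa[i + 1] != PLUS or ca is None or cb is None:
        return MINUS_CAT
    return SAME if ca == cb else DIFF


def pair_dynamics(
    states_a: dict[str, RatioTrack],
    clusters_a: ClusterSet,
    states_b: dict[str, RatioTrack],
    clusters_b: ClusterSet,
) -> pd.DataFrame:
    """Transition table of adjacent-bin pair categories from A to B.

    Rows: pairs categorized Same or Diff in condition A (clustered pairs
    only); columns: their category in B (Same / Diff / Minus); entries are
    row-normalized fractions, so each row sums to 1.
    """
    b2c_a = clusters_a.bin_to_cluster()
    b2c_b = clusters_b.bin_to_cluster()
    table = {r: {c: 0 for c in (SAME, DIFF, MINUS_CAT)} for r in (SAME, DIFF)}
    for chrom, track in states_a.items():
        for i in range(track.lc - 1):
            cat_a = _pair_category(chrom, i, states_a, b2c_a)
            if cat_a == MINUS_CAT:
                continue
            cat_b = _pair_category(chrom, i, states_b, b2c_b)
            table[cat_a][cat_b] += 1
    df = pd.DataFrame(table).T[[SAME, DIFF, MINUS_CAT]]
    if df.to_numpy().sum() == 0:
        raise ValueError("no clustered adjacent pairs in condition A")
    return df.div(df.sum(axis=1), axis=0)


def classify_boundaries(
    clusters_a: ClusterSet, clusters_b: ClusterSet
) -> pd.DataFrame:
    """Label every A boundary bin as condition-common or A-specific.

    Common: also a cluster boundary in B.  A-specific: interior, minus-state
    or unclustered in B.
    """
    bounds_a = clusters_a.boundary_bins(eligible_only=False)
    bounds_b = clusters_b.boundary_bins(eligible_only=False)
    rows = [
        {"chrom": c, "bin": b, "class": "common" if (c, b) in bounds_b else "A_specific"}
        for c, b in sorted(bounds_a)
    ]
    return pd.DataFrame(rows, columns=["chrom", "bin", "class"])


def cluster_jaccard(chrom: str, bin_: int, a: ClusterSet, b: ClusterSet) -> float:
    """Jaccard index of the two clusters containing one bin in A and in B."""
    b2c_a, b2c_b = a.bin_to_cluster(), b.bin_to_cluster()
    if (chrom, bin_) not in b2c_a or (chrom, bin_) not in b2c_b:
        raise ValueError(f"bin {chrom}:{bin_} is not clustered in both conditions")
    ca = next(cl for cl in a.clusters if cl.cid == b2c_a[(chrom, bin_)])
    cb = next(cl for cl in b.clusters if cl.cid == b2c_b[(chrom, bin_)])
    sa, sb = set(ca.bins.tolist()), set(cb.bins.tolist())
    return len(sa & sb) / len(sa | sb)


def de_association(
    de_proportion: dict[tuple[str, int], float],
    a: ClusterSet,
    b: ClusterSet,
    top_frac: float = 0.1,
    bottom_frac: float = 0.1,
) -> dict:
    """Mean cluster Jaccard for bins richest vs poorest in DE genes.

    *de_proportion* maps (chrom, bin) -> proportion of differentially
    expressed genes in that bin, over bins clustered in both conditions.
    Rearrangement near DE genes shows up as mean J(top) < mean J(bottom).
    """
    b2c_a, b2c_b = a.bin_to_cluster(), b.bin_to_cluster()
    items = [
        (loc, prop)
        for loc, prop in de_proportion.items()
        if loc in b2c_a and loc in b2c_b
    ]
    if len(items) < 2:
        raise ValueError("need at least 2 rankable bins clustered in both conditions")
    items.sort(key=lambda kv: (-kv[1], kv[0]))  # descending DE proportion
    n = len(items)
    k_top = max(1, int(round(top_frac * n)))
    k_bot = max(1, int(round(bottom_frac * n)))
    top = items[:k_top]
    bottom = items[-k_bot:]
    j_top = [cluster_jaccard(c, b_, a, b) for (c, b_), _ in top]
    j_bot = [cluster_jaccard(c, b_, a, b) for (c, b_), _ in bottom]
    return {
        "mean_jaccard_top": float(np.mean(j_top)),
        "mean_jaccard_bottom": float(np.mean(j_bot)),
        "difference": float(np.mean(j_bot) - np.mean(j_top)),
        "n_top": k_top,
        "n_bottom": k_bot,
    }
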