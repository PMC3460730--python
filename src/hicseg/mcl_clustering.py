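"""Markov Clustering of the plus-state intra-chromosomal interaction graph.

Nodes are open-chromatin (plus-state) bins; edge weights are raw filtered
contact counts.  Markov Clustering (MCL) alternates expansion (matrix power,
simulating longer random walks) with inflation (entrywise Hadamard power +
column renormalization, sharpening within-cluster flow) until the flow matrix
converges; clusters are read off the attractor structure.  The whole procedure
is deterministic.

Cluster boundaries — the terminal bins of each cluster's contiguous runs —
are the functional unit downstream: insulator (CTCF), cohesin, and
transcription-machinery binding concentrate there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hic_io import ContactMap
from .segmentation import PLUS, RatioTrack

DEFAULT_INFLATION = 3.0
DEFAULT_EXPANSION = 2
DEFAULT_PRUNE = 1e-5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200


@dataclass
class InteractionGraph:
    """Undirected weighted graph over the plus-state bins of one chromosome."""

    chrom: str
    nodes: np.ndarray  # sorted bin indices
    weights: sp.csr_matrix  # (n_nodes, n_nodes), symmetric, zero diagonal

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class Cluster:
    cid: int
    chrom: str
    bins: np.ndarray  # sorted bin indices
    runs: list[tuple[int, int]] = field(default_factory=list)  # inclusive
    boundary: frozenset = frozenset()
    interior: frozenset = frozenset()

    @property
    def has_distal(self) -> bool:
        return len(self.runs) > 1

    @property
    def eligible(self) -> bool:
        return len(self.interior) > 0

    @property
    def size(self) -> int:
        return len(self.bins)


@dataclass
class ClusterSet:
    """Disjoint clusters of bins, possibly spanning several chromosomes."""

    clusters: list[Cluster]
    inflation: float
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def bin_to_cluster(self) -> dict[tuple[str, int], int]:
        out = {}
        for cl in self.clusters:
            for b in cl.bins:
                out[(cl.chrom, int(b))] = cl.cid
        return out

    def boundary_bins(self, eligible_only: bool = False) -> set[tuple[str, int]]:
        out = set()
        for cl in self.clusters:
            if eligible_only and not cl.eligible:
                continue
            out.update((cl.chrom, b) for b in cl.boundary)
        return out

    def interior_bins(self, eligible_only: bool = True) -> set[tuple[str, int]]:
        out = set()
        for cl in self.clusters:
            if eligible_only and not cl.eligible:
                continue
            out.update((cl.chrom, b) for b in cl.interior)
        return out

    def merged(self, others: list["ClusterSet"]) -> "ClusterSet":
        """Combine per-chromosome results, re-numbering cluster ids."""
        all_clusters = list(self.clusters)
        for cs in others:
            all_clusters.extend(cs.clusters)
        out = []
        for cid, cl in enumerate(all_clusters):
            out.append(Cluster(cid, cl.chrom, cl.bins, cl.runs, cl.boundary, cl.interior))
        return ClusterSet(out, self.inflation, self.converged and all(c.converged for c in others))


def build_graph(cmap: ContactMap, states: RatioTrack) -> InteractionGraph:
    """Plus-state bins of one chromosome with raw filtered counts as weights.

    Pass a map already filtered at the minimum pair span (default 20 kb) so
    that near-diagonal random-ligation contacts do not enter the graph.
    Self-pairs are dropped (loop handling belongs to the MCL step).
    """
    if cmap.chrom != states.chrom:
        raise ValueError("contact map and state track refer to different chromosomes")
    nodes = np.flatnonzero(states.state == PLUS)
    sub = cmap.sym()[nodes][:, nodes].tolil()
    sub.setdiag(0)
    return InteractionGraph(cmap.chrom, nodes, sub.tocsr())


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    colsum = np.asarray(M.sum(axis=0)).ravel()
    inv = np.where(colsum > 0, 1.0 / np.maximum(colsum, 1e-300), 0.0)
    return (M @ sp.diags(inv)).tocsr()


def mcl(
    graph: InteractionGraph,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = DEFAULT_EXPANSION,
    prune_threshold: float = DEFAULT_PRUNE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ClusterSet:
    """Deterministic Markov Clustering of an interaction graph.

    Self-loops with weight equal to each node's maximum incident edge weight
    (1 for isolated nodes) are added before column normalization to damp the
    even/odd oscillation of pure random walks.  Iteration: matrix power
    (*expansion*), entrywise power (*inflation*), prune entries below
    *prune_threshold* (each column's maximum is always kept), renormalize —
    until the largest entry change falls below *tol*.  Every node lands in
    exactly one cluster; a node attracted to several clusters goes to the one
    with the largest attractor-row value (ties: lowest cluster index).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    if (graph.weights.data < 0).any():
        raise ValueError("negative edge weights")
    n = graph.n_nodes
    if n == 0:
        return ClusterSet([], inflation)

    W = graph.weights.tocsr().copy()
    maxw = np.zeros(n)
    for i in range(n):
        row = W.data[W.indptr[i] : W.indptr[i + 1]]
        maxw[i] = row.max() if row.size else 1.0
    maxw[maxw == 0] = 1.0
    M = _normalize_columns((W + sp.diags(maxw)).tocsr())

    converged = False
    for _ in range(max_iter):
        prev = M.copy()
        Mx = M
        for _ in range(expansion - 1):
            Mx = (Mx @ M).tocsr()
        Mx.data = np.power(Mx.data, inflation)
        Mx = _prune_keep_colmax(Mx.tocsc(), prune_threshold).tocsr()
        Mx = _normalize_columns(Mx)
        delta = abs(Mx - prev)
        if delta.nnz == 0 or delta.max() < tol:
            M = Mx
            converged = True
            break
        M = Mx

    clusters = _extract_clusters(M, graph, inflation)
    clusters.converged = converged
    return label_boundaries(clusters)


def _prune_keep_colmax(M: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    """Zero entries below *threshold* but never empty a nonzero column."""
    M = M.copy()
    for j in range(M.shape[1]):
        sl = slice(M.indptr[j], M.indptr[j + 1])
        col = M.data[sl]
        if col.size == 0:
            continue
        keep = col >= threshold
        if not keep.any():
            keep = col == col.max()
        M.data[sl] = np.where(keep, col, 0.0)
    M.eliminate_zeros()
    return M


def _extract_clusters(M: sp.csr_matrix, graph: InteractionGraph, inflation: float) -> ClusterSet:
    """Read the partition off a converged MCL flow matrix.

    Attractors are nodes with positive diagonal flow; attractor rows whose
    supports overlap belong to one cluster.  Every node is then assigned to
    the cluster with the largest attractor-row value on its column.
    """
    n = M.shape[0]
    diag = M.diagonal()
    attractors = np.flatnonzero(diag > 0)
    if attractors.size == 0:  # non-converged edge case: everything separate
        attractors = np.arange(n)

    # union attractors whose row supports intersect
    parent = {int(a): int(a) for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[int, int] = {}  # column -> attractor that reaches it
    for a in attractors:
        support = M.indices[M.indptr[a] : M.indptr[a + 1]]
        for c in support:
            c = int(c)
            if c in owner and find(owner[c]) != find(int(a)):
                ra, rb = sorted((find(owner[c]), find(int(a))))
                parent[rb] = ra
            owner.setdefault(c, int(a))

    roots = sorted({find(int(a)) for a in attractors})
    root_to_cid = {r: i for i, r in enumerate(roots)}

    # per-column best attractor value decides membership
    best_val = np.full(n, -1.0)
    assign = np.full(n, -1, dtype=np.int64)
    for a in sorted(attractors):
        cid = root_to_cid[find(int(a))]
        sl = slice(M.indptr[a], M.indptr[a + 1])
        for c, v in zip(M.indices[sl], M.data[sl]):
            if v > best_val[c] or (v == best_val[c] and cid < assign[c]):
                best_val[c] = v
                assign[c] = cid
    next_cid = len(roots)
    for c in np.flatnonzero(assign < 0):  # unreachable column: singleton
        assign[c] = next_cid
        next_cid += 1

    clusters = []
    for cid in range(next_cid):
        members = graph.nodes[np.flatnonzero(assign == cid)]
        if members.size:
            clusters.append(Cluster(len(clusters), graph.chrom, np.sort(members)))
    return ClusterSet(clusters, inflation)


def label_boundaries(clusters: ClusterSet) -> ClusterSet:
    """Split each cluster into contiguous runs; mark run-terminal bins boundary.

    A cluster is *eligible* for enrichment analysis iff it keeps at least one
    interior bin; it is *distal* iff its bins form more than one run.
    """
    for cl in clusters.clusters:
        bins = np.sort(cl.bins)
        runs = []
        start = 0
        for i in range(1, len(bins) + 1):
            if i == len(bins) or bins[i] != bins[i - 1] + 1:
                runs.append((int(bins[start]), int(bins[i - 1])))
                start = i
        boundary, interior = set(), set()
        for r0, r1 in runs:
            boundary.add(r0)
            boundary.add(r1)
            interior.update(range(r0 + 1, r1))
        cl.runs = runs
        cl.boundary = frozenset(boundary)
        cl.interior = frozenset(interior)
        cl.bins = bins
    return clusters


def cluster_chromosomes(
    maps: dict[str, ContactMap],
    tracks: dict[str, RatioTrack],
    inflation: float = DEFAULT_INFLATION,
    **mcl_kwargs,
) -> ClusterSet:
    """Run MCL per chromosome and merge into one genome-wide ClusterSet."""
    parts = []
    for chrom in maps:
        graph = build_graph(maps[chrom], tracks[chrom])
        parts.append(mcl(graph, inflation=inflation, **mcl_kwargs))
    if not parts:
        return ClusterSet([], inflation)
    return parts[0].merged(parts[1:])


def clusterset_from_bins(
    bin2cluster: dict[tuple[str, int], int], inflation: float = DEFAULT_INFLATION
) -> ClusterSet:
    """Rebuild a ClusterSet from a (chrom, bin) -> cluster id mapping.

    Used to re-read cluster assignments from the per-bin BED output; the
    round trip is lossless at bin resolution.
    """
    groups: dict[int, tuple[str, list[int]]] = {}
    for (chrom, b), cid in bin2cluster.items():
        groups.setdefault(cid, (chrom, []))[1].append(b)
    clusters = [
        Cluster(cid, chrom, np.sort(np.array(bins)))
        for cid, (chrom, bins) in sorted(groups.items())
    ]
    return label_boundaries(ClusterSet(clusters, inflation))


def inflation_sweep(graph: InteractionGraph, inflations: list[float], **mcl_kwargs) -> pd.DataFrame:
    """Cluster at each inflation; report boundary persistence between steps.

    ``shared_frac`` at row k is the fraction of boundary bins at inflation
    k-1 that are still boundary bins at inflation k (NaN for the first row).
    A plateau of this fraction locates the stable inflation regime.
    """
    if list(inflations) != sorted(inflations):
        raise ValueError("inflations must be sorted ascending")
    rows = []
    prev_bounds: set | None = None
    for inf in inflations:
        cs = mcl(graph, inflation=inf, **mcl_kwargs)
        bounds = {b for cl in cs.clusters for b in cl.boundary}
        shared = np.nan
        if prev_bounds is not None and prev_bounds:
            shared = len(prev_bounds & bounds) / len(prev_bounds)
        rows.append({"inflation": inf, "n_clusters": cs.n_clusters, "shared_frac": shared})
        prev_bounds = bounds
    return pd.DataFrame(rows)
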