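import numpy as np
import pytest
import scipy.sparse as sp

from hicseg import mcl_clustering as mc
from hicseg import segmentation as seg
from hicseg import synthetic_data as sd
from hicseg.hic_io import BinGrid, ContactMap


@pytest.fixture
def small_grid():
    return BinGrid({"chr1": 1_000_000, "chr2": 500_000}, bin_size=100_000)


def graph_from_dense(W, chrom="chrT", nodes=None):
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    nodes = np.arange(n) if nodes is None else np.asarray(nodes)
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return mc.InteractionGraph(chrom, nodes, sp.csr_matrix(W))


def random_contact_map(lc, rng, density=0.5, max_count=50, chrom="chrR"):
    n_entries = max(1, int(density * lc * (lc + 1) / 2))
    m = rng.integers(0, lc, size=n_entries)
    n = rng.integers(0, lc, size=n_entries)
    c = rng.integers(1, max_count, size=n_entries)
    return ContactMap.from_arrays(chrom, lc, m, n, c)


@pytest.fixture(scope="session")
def default_pipeline():
    """One strong-signal synthetic genome run end to end (shared, read-only)."""
    plan = sd.make_plan(1000, seed=11)
    params = sd.SimParams()
    cmap = sd.sample_contacts(plan, params, seed=12)
    grid = BinGrid(plan.chrom_sizes, plan.bin_size)
    track, regions = seg.segment(cmap, grid)
    filtered = cmap.drop_short_range(20_000, plan.bin_size)
    graph = mc.build_graph(filtered, track)
    clusters = mc.mcl(graph)
    peaks, genes = sd.sample_features(plan, params, seed=13)
    return {
        "plan": plan,
        "params": params,
        "cmap": cmap,
        "filtered": filtered,
        "grid": grid,
        "track": track,
        "regions": regions,
        "graph": graph,
        "clusters": clusters,
        "peaks": peaks,
        "genes": genes,
    }
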