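"""Two-state chromatin segmentation from the short/long-range interaction ratio.

The model: random short-range contacts are detected more readily in open
chromatin than in closed chromatin.  After removing the genome-wide distance
decay (each bin-pair count divided by the chromosome mean at the same bin
distance), a per-bin log ratio of summed short-range to summed long-range
normalized contacts separates open ("plus", R > 0) from closed ("minus",
R < 0) bins; bins with no usable signal or inside assembly gaps are "gap".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .hic_io import BinGrid, ContactMap, IntervalSet

PLUS, MINUS, GAP = 1, -1, 0

#: default short-range window in bins (1 Mb at the default 100 kb bin size)
DEFAULT_D = 10


class NormalizedMap:
    """Distance-normalized contact map for one chromosome.

    ``norm[m, n] = IV[m, n] / (sum of IV at distance |m-n| / (lc - |m-n|))``;
    the denominator is the mean over *all* lc-t bin pairs at that distance
    (zero-count pairs included).  By construction the mean of the normalized
    values over each distance with signal equals 1.
    """

    def __init__(self, chrom: str, lc: int, upper: sp.csr_matrix):
        self.chrom = chrom
        self.lc = lc
        self.upper = upper.tocsr()

    def sym(self) -> sp.csr_matrix:
        up = self.upper
        return (up + up.T - sp.diags(up.diagonal())).tocsr()

    def per_distance_means(self) -> np.ndarray:
        """Mean normalized value at each distance (NaN where no pairs exist)."""
        coo = self.upper.tocoo()
        t = coo.col - coo.row
        sums = np.bincount(t, weights=coo.data, minlength=self.lc)
        npairs = self.lc - np.arange(self.lc)
        return sums / npairs


@dataclass
class RatioTrack:
    """Per-bin interaction ratio and plus/minus/gap state for one chromosome."""

    chrom: str
    R: np.ndarray  # float, NaN = undefined
    d: int
    state: np.ndarray = field(default=None)  # int8 in {PLUS, MINUS, GAP}

    @property
    def lc(self) -> int:
        return len(self.R)

    def __post_init__(self):
        if self.state is None:
            self.state = np.full(self.lc, GAP, dtype=np.int8)


@dataclass(frozen=True)
class StateRegion:
    """Maximal run of consecutive bins sharing one state (end inclusive)."""

    chrom: str
    start: int
    end: int
    state: int

    @property
    def n_bins(self) -> int:
        return self.end - self.start + 1


def normalize_by_distance(cmap: ContactMap) -> NormalizedMap:
    """Divide each bin-pair count by the chromosome mean at its bin distance.

    Distances whose total count is zero stay zero.  Doubling every raw count
    leaves the result unchanged (the statistic is a ratio).
    """
    if cmap.lc < 2:
        raise ValueError("need at least 2 bins to normalize")
    coo = cmap.upper.tocoo()
    t = coo.col - coo.row
    sums = np.bincount(t, weights=coo.data, minlength=cmap.lc)
    npairs = cmap.lc - np.arange(cmap.lc)
    means = sums / npairs
    with np.errstate(divide="ignore", invalid="ignore"):
        data = np.where(means[t] > 0, coo.data / means[t], 0.0)
    norm = sp.coo_matrix((data, (coo.row, coo.col)), shape=(cmap.lc, cmap.lc)).tocsr()
    return NormalizedMap(cmap.chrom, cmap.lc, norm)


def interaction_ratio(
    norm: NormalizedMap, d: int = DEFAULT_D, mode: str = "as_printed"
) -> RatioTrack:
    """Per-bin log ratio of short-range to long-range normalized contacts.

    For bin i the short-range side gathers normalized contacts with
    neighbours j in [i-d, i+d] (clipped to the chromosome, self term
    excluded) and the long-range side gathers contacts with k > i+d
    (``as_printed``) or with both tails |k-i| > d (``symmetric``).  Each side
    is divided by its number of bin pairs before taking the ratio, so
    R_i = ln(mean short-range NormIV / mean long-range NormIV): since
    normalized contacts average 1 at every distance, R is centred at zero
    for a featureless bin no matter where it sits on the chromosome, and its
    sign reads out short-range contact excess (open chromatin) versus
    deficit (closed chromatin).  R_i is undefined when either side has no
    pairs or no signal — under ``as_printed`` the trailing d+1 bins have an
    empty long-range side and are therefore always undefined.
    """
    if not 1 <= d < norm.lc:
        raise ValueError(f"d must satisfy 1 <= d < lc (got d={d}, lc={norm.lc})")
    if mode not in ("as_printed", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    N = norm.sym()
    lc = norm.lc
    indptr, indices, data = N.indptr, N.indices, N.data
    R = np.full(lc, np.nan)
    for i in range(lc):
        j = indices[indptr[i] : indptr[i + 1]]
        v = data[indptr[i] : indptr[i + 1]]
        near = (np.abs(j - i) <= d) & (j != i)
        S = v[near].sum()
        L = v[j > i + d].sum()
        n_short = min(lc - 1, i + d) - max(0, i - d)  # window size minus self
        n_long = lc - 1 - (i + d)
        if mode == "symmetric":
            L += v[j < i - d].sum()
            n_long += max(0, i - d)
        if S > 0 and L > 0 and n_short > 0 and n_long > 0:
            R[i] = np.log((S / n_short) / (L / n_long))
    return RatioTrack(norm.chrom, R, d)


def assign_states(
    track: RatioTrack, gaps: IntervalSet | None, grid: BinGrid
) -> tuple[RatioTrack, list[StateRegion]]:
    """Assign plus/minus/gap per bin and emit maximal same-state regions.

    Sign of R decides plus/minus (R == 0 -> minus, a deterministic tie rule).
    Bins with undefined R, or overlapping any supplied assembly-gap interval,
    are gap regardless of R.  Without a gap file, zero-coverage bins already
    have undefined R and land in the gap state.
    """
    state = np.where(np.isnan(track.R), GAP, np.where(track.R > 0, PLUS, MINUS)).astype(np.int8)
    if gaps is not None:
        sub = gaps.df[gaps.df["chrom"] == track.chrom]
        for _, rec in sub.iterrows():
            b0 = rec["start"] // grid.bin_size
            b1 = min((rec["end"] - 1) // grid.bin_size, track.lc - 1)
            state[b0 : b1 + 1] = GAP
    track.state = state
    regions: list[StateRegion] = []
    start = 0
    for i in range(1, track.lc + 1):
        if i == track.lc or state[i] != state[start]:
            regions.append(StateRegion(track.chrom, start, i - 1, int(state[start])))
            start = i
    return track, regions


def sign_concordance(tracks: dict[str, RatioTrack], reference: dict[str, np.ndarray]) -> float:
    """Percent of bins whose ratio sign matches an external signed track.

    Comparable bins: non-gap in *tracks* and finite, nonzero in *reference*
    (R == 0 counts as minus, matching the state rule).  Typical use: compare
    against the first principal component of the contact correlation matrix.
    """
    agree = comparable = 0
    for chrom, track in tracks.items():
        if chrom not in reference:
            continue
        ref = np.asarray(reference[chrom], dtype=float)
        ok = (track.state != GAP) & np.isfinite(ref) & (ref != 0)
        sign_a = np.where(track.state[ok] == PLUS, 1, -1)
        sign_b = np.where(ref[ok] > 0, 1, -1)
        comparable += int(ok.sum())
        agree += int((sign_a == sign_b).sum())
    if comparable == 0:
        raise ValueError("no comparable bins between track and reference")
    return 100.0 * agree / comparable


def percentile_rank(tracks: dict[str, RatioTrack]) -> dict[str, np.ndarray]:
    """Percentile in (0, 100] of each non-gap bin's ratio, ranked genome-wide.

    Ties share the mean rank; gap bins are NaN.
    """
    chroms = list(tracks)
    values, owners = [], []
    for chrom in chroms:
        track = tracks[chrom]
        idx = np.flatnonzero(track.state != GAP)
        values.append(track.R[idx])
        owners.append((chrom, idx))
    allv = np.concatenate(values) if values else np.array([])
    if allv.size == 0:
        raise ValueError("no non-gap bins to rank")
    pct = 100.0 * rankdata(allv, method="average") / allv.size
    out = {}
    pos = 0
    for (chrom, idx), vals in zip(owners, values):
        arr = np.full(tracks[chrom].lc, np.nan)
        arr[idx] = pct[pos : pos + len(idx)]
        out[chrom] = arr
        pos += len(idx)
    return out


def segment(
    cmap: ContactMap,
    grid: BinGrid,
    d: int = DEFAULT_D,
    mode: str = "as_printed",
    gaps: IntervalSet | None = None,
) -> tuple[RatioTrack, list[StateRegion]]:
    """Convenience pipeline: normalize, compute ratio, assign states."""
    norm = normalize_by_distance(cmap)
    track = interaction_ratio(norm, d=d, mode=mode)
    return assign_states(track, gaps, grid)
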