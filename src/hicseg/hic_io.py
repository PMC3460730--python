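"""Readers and writers for Hi-C pair files, genomic annotations, and track output.

The unit of analysis throughout the package is the fixed-size genomic bin
(default 100 kb).  This module owns the containers that everything else
consumes: :class:`BinGrid` (the bin coordinate system), :class:`ContactMap`
(per-chromosome symmetric bin-pair counts), :class:`IntervalSet` (BED-style
features) and :class:`GeneTable` (TSS + expression).  It also writes the three
canonical output files: a fixed-step wiggle of the interaction ratio, a per-bin
state/cluster BED, and a plain-text cluster file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_BIN_SIZE = 100_000

#: Column indices of the default mapped-pair dialect:
#: read id, chrom1, pos1, strand1, chrom2, pos2, strand2 (extra columns ignored).
DEFAULT_PAIR_COLUMNS = {"chrom1": 1, "pos1": 2, "chrom2": 4, "pos2": 5}


class MalformedLineError(ValueError):
    """A pair-file line that cannot be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, line: str, reason: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {reason}: {line.rstrip()!r}")


@dataclass(frozen=True)
class BinGrid:
    """Fixed-size binning of a genome.

    Bin ``i`` on a chromosome covers ``[i*bin_size, (i+1)*bin_size)`` in
    0-based half-open coordinates.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def lc(self, chrom: str) -> int:
        """Number of bins on *chrom* (ceil of length / bin_size)."""
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def bin_of(self, chrom: str, pos0: int) -> int:
        """Bin index of a 0-based position, clamped to the last bin."""
        return min(pos0 // self.bin_size, self.lc(chrom) - 1)

    def bin_span(self, chrom: str, i: int) -> tuple[int, int]:
        """0-based half-open genomic interval covered by bin *i*."""
        return i * self.bin_size, min((i + 1) * self.bin_size, self.chrom_sizes[chrom])


@dataclass(frozen=True)
class ReadPair:
    """One intra- or inter-chromosomal mapped read pair (positions 1-based)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> int:
        if not self.intra:
            raise ValueError("span undefined for inter-chromosomal pair")
        return abs(self.pos2 - self.pos1)


@dataclass
class PairFilterStats:
    """Bookkeeping for :func:`parse_pairs`: kept + dropped == lines seen."""

    kept: int = 0
    dropped_inter: int = 0
    dropped_short: int = 0
    dropped_unknown_chrom: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.dropped_inter + self.dropped_short + self.dropped_unknown_chrom


class ContactMap:
    """Symmetric bin-pair interaction counts for one chromosome.

    Counts are stored once as an upper-triangular sparse matrix (``m <= n``);
    :meth:`sym` materialises the full symmetric view.
    """

    def __init__(self, chrom: str, lc: int, upper: sp.csr_matrix):
        if upper.shape != (lc, lc):
            raise ValueError("matrix shape does not match bin count")
        if (upper.data < 0).any():
            raise ValueError("negative interaction counts")
        self.chrom = chrom
        self.lc = lc
        self.upper = upper.tocsr()
        self.upper.eliminate_zeros()

    @classmethod
    def from_arrays(cls, chrom: str, lc: int, m, n, counts) -> "ContactMap":
        m = np.asarray(m, dtype=np.int64)
        n = np.asarray(n, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        lo, hi = np.minimum(m, n), np.maximum(m, n)
        if lc > 0 and len(hi) and hi.max() >= lc:
            raise ValueError("bin index out of range")
        mat = sp.coo_matrix((counts, (lo, hi)), shape=(lc, lc)).tocsr()
        mat.sum_duplicates()
        return cls(chrom, lc, mat)

    @classmethod
    def from_dense(cls, chrom: str, dense) -> "ContactMap":
        dense = np.asarray(dense, dtype=np.float64)
        if not np.allclose(dense, dense.T):
            raise ValueError("dense contact matrix must be symmetric")
        return cls(chrom, dense.shape[0], sp.csr_matrix(np.triu(dense)))

    def sym(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once)."""
        up = self.upper
        return (up + up.T - sp.diags(up.diagonal())).tocsr()

    @property
    def total(self) -> float:
        return float(self.upper.sum())

    def scaled(self, factor: float) -> "ContactMap":
        return ContactMap(self.chrom, self.lc, self.upper * factor)

    def drop_short_range(self, min_span: int, bin_size: int) -> "ContactMap":
        """Remove bin pairs whose center-to-center distance is below *min_span*.

        Bin-level analogue of the read-pair span filter for pre-binned input:
        a pair at bin distance t spans t*bin_size; pairs with
        t*bin_size < min_span (including the diagonal) are dropped.
        """
        coo = self.upper.tocoo()
        keep = (coo.col - coo.row) * bin_size >= min_span
        mat = sp.coo_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=(self.lc, self.lc)
        ).tocsr()
        return ContactMap(self.chrom, self.lc, mat)

    def distance_totals(self) -> np.ndarray:
        """Total count at each bin distance t (length lc)."""
        coo = self.upper.tocoo()
        return np.bincount(coo.col - coo.row, weights=coo.data, minlength=self.lc)


@dataclass
class IntervalSet:
    """BED-semantics genomic intervals (0-based half-open)."""

    df: pd.DataFrame  # columns: chrom, start, end, [name]

    def __post_init__(self):
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            rec = self.df.iloc[idx]
            raise ValueError(
                f"interval with start >= end: {rec['chrom']}:{rec['start']}-{rec['end']}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"] + self.df["end"]) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})

    def to_bins(self, grid: BinGrid) -> pd.DataFrame:
        """Assign each interval to the bin containing its midpoint.

        Intervals on chromosomes absent from the grid are dropped.
        """
        mid = self.midpoints()
        mid = mid[mid["chrom"].isin(grid.chrom_sizes)].copy()
        mid["bin"] = [grid.bin_of(c, p) for c, p in zip(mid["chrom"], mid["pos"])]
        return mid[["chrom", "bin"]].reset_index(drop=True)

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneTable:
    """Genes with TSS coordinates and (optionally missing) expression values."""

    df: pd.DataFrame  # columns: gene, chrom, tss, strand, expression

    def __len__(self) -> int:
        return len(self.df)

    def tss_bins(self, grid: BinGrid) -> pd.DataFrame:
        sub = self.df[self.df["chrom"].isin(grid.chrom_sizes)].copy()
        sub["bin"] = [grid.bin_of(c, p) for c, p in zip(sub["chrom"], sub["tss"])]
        return sub[["gene", "chrom", "bin", "expression"]].reset_index(drop=True)

    def subset(self, gene_ids: Iterable[str]) -> "GeneTable":
        ids = set(gene_ids)
        return GeneTable(self.df[self.df["gene"].isin(ids)].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def parse_pairs(
    path,
    grid: BinGrid,
    intra_only: bool = True,
    min_span: int = 0,
    columns: Mapping[str, int] | None = None,
    stats: PairFilterStats | None = None,
) -> Iterator[ReadPair]:
    """Stream read pairs from a tab-delimited mapped-pair file.

    *columns* maps the keys chrom1/pos1/chrom2/pos2 to 0-based column indices
    (default: the 7-column read-id/chrom/pos/strand dialect).  Pairs on
    chromosomes unknown to *grid* are skipped with a warning count; intra
    pairs with span < *min_span* and (optionally) inter-chromosomal pairs are
    dropped.  Pass a :class:`PairFilterStats` to recover the kept/dropped
    bookkeeping.
    """
    cols = dict(DEFAULT_PAIR_COLUMNS if columns is None else columns)
    st = stats if stats is not None else PairFilterStats()
    needed = max(cols.values()) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < needed:
                raise MalformedLineError(lineno, line, "too few columns")
            try:
                pair = ReadPair(
                    chrom1=parts[cols["chrom1"]],
                    pos1=int(parts[cols["pos1"]]),
                    chrom2=parts[cols["chrom2"]],
                    pos2=int(parts[cols["pos2"]]),
                )
            except ValueError as exc:
                raise MalformedLineError(lineno, line, str(exc)) from None
            if pair.pos1 < 1 or pair.pos2 < 1:
                raise MalformedLineError(lineno, line, "position < 1")
            if pair.chrom1 not in grid.chrom_sizes or pair.chrom2 not in grid.chrom_sizes:
                st.dropped_unknown_chrom += 1
                continue
            if not pair.intra:
                if intra_only:
                    st.dropped_inter += 1
                    continue
            elif pair.span < min_span:
                st.dropped_short += 1
                continue
            st.kept += 1
            yield pair
    if st.dropped_unknown_chrom and stats is None:
        warnings.warn(f"skipped {st.dropped_unknown_chrom} pairs on unknown chromosomes")


def bin_pairs(pairs: Iterable[ReadPair], grid: BinGrid) -> dict[str, ContactMap]:
    """Count intra-chromosomal pairs into per-chromosome contact maps.

    A read end belongs to the bin containing its starting position (1-based
    input converted to 0-based).  Positions beyond the chromosome end are
    clamped to the last bin with a warning.
    """
    acc: dict[str, list[list[int]]] = {}
    clamped = 0
    for pair in pairs:
        if not pair.intra:
            raise ValueError("bin_pairs expects intra-chromosomal pairs")
        chrom = pair.chrom1
        size = grid.chrom_sizes[chrom]
        if pair.pos1 > size or pair.pos2 > size:
            clamped += 1
        m = grid.bin_of(chrom, min(pair.pos1 - 1, size - 1))
        n = grid.bin_of(chrom, min(pair.pos2 - 1, size - 1))
        acc.setdefault(chrom, [[], []])
        acc[chrom][0].append(m)
        acc[chrom][1].append(n)
    if clamped:
        warnings.warn(f"clamped {clamped} positions beyond chromosome end to last bin")
    return {
        chrom: ContactMap.from_arrays(chrom, grid.lc(chrom), mm, nn, np.ones(len(mm)))
        for chrom, (mm, nn) in acc.items()
    }


def read_triplets(path, chrom: str, lc: int) -> ContactMap:
    """Read a pre-binned (bin, bin, count) triplet file for one chromosome."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["m", "n", "count"], comment="#")
    return ContactMap.from_arrays(chrom, lc, df["m"], df["n"], df["count"])


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (comment/track lines ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                rec["name"] = parts[3]
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalSet(df)


def read_genes(path) -> GeneTable:
    """Read a tab-delimited gene table: gene, chrom, tss, strand, expression.

    A header line is auto-detected; missing expression values are allowed.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    first = df.iloc[0]
    if not str(first[2]).lstrip("-").isdigit():  # header present
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :5]
    df.columns = ["gene", "chrom", "tss", "strand", "expression"]
    df["tss"] = df["tss"].astype(int)
    df["expression"] = pd.to_numeric(df["expression"], errors="coerce")
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    return GeneTable(df)


def read_track(path, grid: BinGrid) -> dict[str, np.ndarray]:
    """Read a bedGraph or fixed-step wiggle into per-bin values.

    Values are averaged into grid bins weighted by covered length; bins with
    no coverage are NaN.
    """
    weight: dict[str, np.ndarray] = {}
    wsum: dict[str, np.ndarray] = {}

    def add(chrom: str, start: int, end: int, value: float):
        if chrom not in grid.chrom_sizes:
            return
        if start >= end:
            raise ValueError(f"track record with start >= end: {chrom}:{start}-{end}")
        lc = grid.lc(chrom)
        if chrom not in weight:
            weight[chrom] = np.zeros(lc)
            wsum[chrom] = np.zeros(lc)
        b0, b1 = start // grid.bin_size, min((end - 1) // grid.bin_size, lc - 1)
        for b in range(b0, b1 + 1):
            lo, hi = b * grid.bin_size, (b + 1) * grid.bin_size
            cov = min(end, hi) - max(start, lo)
            weight[chrom][b] += cov
            wsum[chrom][b] += cov * value

    with open(path) as fh:
        chrom, pos, step, span = None, 0, 0, 0
        mode = "bedgraph"
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
                mode = "fixed"
                continue
            if mode == "fixed":
                add(chrom, pos, pos + span, float(line))
                pos += step
            else:
                parts = line.split()
                add(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))

    out = {}
    for chrom in weight:
        with np.errstate(invalid="ignore"):
            vals = np.where(weight[chrom] > 0, wsum[chrom] / np.maximum(weight[chrom], 1e-300), np.nan)
        out[chrom] = vals
    return out


def write_outputs(ratio_tracks, clusters, grid: BinGrid, prefix) -> dict[str, Path]:
    """Write the three canonical output files.

    ``<prefix>.wig``     fixed-step wiggle of the interaction ratio (1-based,
                         step = bin size; gap bins omitted by re-declaring
                         the step header after each gap),
    ``<prefix>.bed``     one record per bin: state (+/-/gap) and cluster id,
    ``<prefix>.cluster`` one line per cluster: id, flags, then chrom:start-end
                         spans of its contiguous runs.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    wig_path = prefix.with_suffix(".wig")
    bed_path = prefix.with_suffix(".bed")
    cluster_path = prefix.with_suffix(".cluster")

    state_char = {1: "+", -1: "-", 0: "gap"}
    bin2cluster = clusters.bin_to_cluster() if clusters is not None else {}

    with open(wig_path, "w") as wig:
        wig.write("track type=wiggle_0 name=interaction_ratio\n")
        for chrom, track in ratio_tracks.items():
            run_start = None
            for i in range(track.lc):
                defined = np.isfinite(track.R[i])
                if defined and run_start is None:
                    wig.write(
                        f"fixedStep chrom={chrom} start={i * grid.bin_size + 1} "
                        f"step={grid.bin_size} span={grid.bin_size}\n"
                    )
                    run_start = i
                if defined:
                    wig.write(f"{track.R[i]:.6g}\n")
                else:
                    run_start = None

    with open(bed_path, "w") as bed:
        for chrom, track in ratio_tracks.items():
            for i in range(track.lc):
                start, end = grid.bin_span(chrom, i)
                cid = bin2cluster.get((chrom, i), -1)
                name = f"{state_char[int(track.state[i])]};cluster={cid}"
                bed.write(f"{chrom}\t{start}\t{end}\t{name}\n")

    with open(cluster_path, "w") as cf:
        if clusters is not None:
            for cl in clusters.clusters:
                spans = ",".join(
                    f"{cl.chrom}:{r0 * grid.bin_size}-{min((r1 + 1) * grid.bin_size, grid.chrom_sizes[cl.chrom])}"
                    for r0, r1 in cl.runs
                )
                flags = ("distal" if cl.has_distal else "contiguous") + (
                    ";eligible" if cl.eligible else ";ineligible"
                )
                cf.write(f"cluster_{cl.cid}\t{flags}\t{spans}\n")

    return {"wig": wig_path, "bed": bed_path, "cluster": cluster_path}


def read_state_bed(path, grid: BinGrid) -> tuple[dict[str, np.ndarray], dict[tuple[str, int], int]]:
    """Re-read a per-bin state/cluster BED written by :func:`write_outputs`.

    Returns per-chromosome state arrays (+1/-1/0) and a (chrom, bin) ->
    cluster id mapping (-1 entries omitted).
    """
    states = {c: np.zeros(grid.lc(c), dtype=np.int8) for c in grid.chroms}
    bin2cluster: dict[tuple[str, int], int] = {}
    code = {"+": 1, "-": -1, "gap": 0}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            chrom, start, name = parts[0], int(parts[1]), parts[3]
            state_s, cid_s = name.split(";")
            cid = int(cid_s.split("=")[1])
            b = start // grid.bin_size
            states[chrom][b] = code[state_s]
            if cid >= 0:
                bin2cluster[(chrom, b)] = cid
    return states, bin2cluster
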