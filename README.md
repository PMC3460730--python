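# hicseg

Two-state chromatin segmentation and Markov clustering of Hi-C
intra-chromosomal contact maps, for genomicists who want compartment-like
states and sub-compartment cluster boundaries from mapped Hi-C read pairs
without principal-component analysis.

## What it computes

Binned contact counts `IV_mn` (100 kb bins by default) are first freed of the
genomic distance decay:

    NormIV_mn = IV_mn / ( Σ_{|p−q|=|m−n|} IV_pq / (lc − |m−n|) )

so that the mean normalized contact at every bin distance is 1 (`lc` = bins
on the chromosome).  Each bin then gets an **interaction ratio**

    R_i = ln( mean short-range NormIV (within d bins of i)
            / mean long-range NormIV (beyond d bins) ),

whose sign calls the bin's state: `plus` (open, element-rich chromatin,
short-range contact excess) or `minus` (closed, element-poor); bins without
usable signal or inside assembly gaps are `gap`.  Plus-state bins are then
clustered with deterministic **Markov Clustering** (expansion = matrix power,
inflation = Hadamard power + renormalization, default inflation 3.0) on the
graph of contacts filtered at a 20 kb minimum pair span.  Terminal bins of
each cluster's contiguous runs are **boundary** bins — where insulator
(CTCF), cohesin and transcription-machinery binding concentrate — and
interior bins are the matched control group for enrichment tests (binomial
tails, BH adjustment).  A distance-preserving simulated null (same number of
contacts at every genomic distance, positions randomized) benchmarks the
within- vs across-cluster contact fold, and two-condition comparisons
quantify boundary and cluster dynamics between cell types.

## Worked example

Everything runs on generated data, so a complete demo needs no downloads:

```
hicseg simulate --n-bins 300 --seed 11 -o sim
printf 'chrS\t30000000\n' > chrom.sizes
hicseg cluster -f sim/pairs.txt --chrom-sizes chrom.sizes -o out/run
```

which prints

```
pairs: kept 104869, inter 0, short-span 0, unknown-chrom 0
clusters        24      distal  1
```

— 104,869 read pairs binned, 24 clusters of open-chromatin bins found, one
of them containing distal (non-contiguous) bins.  Three files are written:
`out/run.wig` (interaction ratio track), `out/run.bed` (per-bin state and
cluster id, e.g. `chrS  0  100000  +;cluster=0`) and `out/run.cluster`
(one line per cluster, e.g. `cluster_0  contiguous;eligible  chrS:0-700000`).
Boundary enrichment of the simulated peak and gene tracks:

```
hicseg enrich --bed out/run.bed --chrom-sizes chrom.sizes \
       --peaks sim/peaks.bed --genes sim/genes.tsv -o enrich.tsv
```

| feature      | fold | adjusted p | meaning                                   |
|--------------|------|------------|-------------------------------------------|
| peaks        | 1.44 | 2.9e-02    | peak density, boundary vs interior bins    |
| tss          | 2.14 | 2.2e-05    | TSS density, boundary vs interior bins     |
| expr_top25   | 19.95| 2.4e-12    | top-quartile genes concentrate at boundaries |
| expr_middle50| 1.42 | 9.7e-02    |                                            |
| expr_bottom25| 0.24 | 9.9e-01    | low-expressed genes avoid boundaries       |

The fold ordering top > middle > bottom reproduces the expected association
between transcriptional activity and cluster boundaries.  `hicseg segment`
runs only the state-calling step, `hicseg compare` contrasts two clustered
BED files (pair-category transitions, common vs condition-specific
boundaries).  Every command writes a `.provenance.json` sidecar with its
parameters and input hashes.

## Layout

- `src/hicseg/hic_io.py` — pair/BED/gene/track parsers, contact maps, output writers
- `src/hicseg/segmentation.py` — distance normalization, interaction ratio, states
- `src/hicseg/mcl_clustering.py` — interaction graph, Markov Clustering, boundaries
- `src/hicseg/stats.py` — within/across fold, simulated null, enrichment tests
- `src/hicseg/dynamics.py` — two-condition state/cluster comparisons
- `src/hicseg/synthetic_data.py` — seeded generator with planted structure
- `src/hicseg/cli.py` — `hicseg` command-line interface
- `docs/methods.md` — model, assumptions, parameter defaults, limitations
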