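# Methods

## The model

Hi-C read pairs mark pairs of genomic loci that were physically close in the
nucleus.  After binning both read ends into fixed 100 kb bins, the count
`IV[m, n]` of pairs joining bins m and n on one chromosome is dominated by the
genomic distance between the bins: contact frequency decays roughly as a power
law in `t = |m - n|`.  The package's working assumption is that *random
short-range contacts are detected more readily in open chromatin than in
closed chromatin*, so after the distance decay is removed, a bin's short-range
contact excess or deficit reads out its chromatin environment.

### Distance normalization

Each count is divided by the chromosome-wide mean count at the same bin
distance,

    NormIV[m, n] = IV[m, n] / ( sum_{|p-q| = t} IV[p, q] / (lc - t) ),

where `lc` is the number of bins on the chromosome and the denominator's mean
runs over **all** `lc - t` bin pairs at distance `t`, zero-count pairs
included.  By construction the mean normalized value at every distance with
signal is exactly 1; distances with no counts anywhere stay zero.  The
statistic is a ratio, so rescaling all counts (sequencing depth) changes
nothing downstream.

### Interaction ratio and two-state segmentation

For bin i with short-range window `d` (default 10 bins = 1 Mb):

    R_i = ln( mean of NormIV[i, j] over j in [i-d, i+d], j != i
            / mean of NormIV[i, k] over the long-range side ),

with the long-range side either strictly downstream of `i+d` (mode
`as_printed`, the default, under which the trailing `d+1` bins of every
chromosome have an empty long-range side and are reported as gaps) or both
tails (mode `symmetric`).  Each side is divided by its number of bin pairs.
This normalization per pair is deliberate: a *sum* over a long-range side of
up to `lc` pairs grows with the distance to the chromosome end, so the sign of
a sum-ratio would encode a bin's position rather than its chromatin state;
the ratio of per-pair means is position-independent and centred at zero for a
featureless bin, which is what makes the sign usable as a state call and
reproduces a roughly 40/60 plus/minus split under the default synthetic
conditions.  The self-pair `NormIV[i, i]` is excluded from the short side:
distance-0 counts are dominated by self-ligation artifacts and carry no
information about the short/long contrast.

States: `plus` iff R_i > 0, `minus` iff R_i <= 0 (the R = 0 tie is assigned
minus — arbitrary but deterministic and measure-zero in practice), `gap` when
R_i is undefined or the bin overlaps a supplied assembly-gap interval.  When
no gap annotation is given, bins with no usable signal (zero counts on either
side) have undefined R and land in the gap state automatically, which is the
observable proxy for assembly gaps.  The log base is natural; only the sign
is used downstream, and the sign is base-invariant.

## Markov clustering of open regions

Plus-state bins of each chromosome form a graph whose edge weights are raw
counts from a map filtered at a minimum pair span (default 20 kb) to remove
random-ligation contacts; raw counts rather than normalized values are used
because the cluster validation statistic is defined on counts (a flag switches
to normalized weights).  Markov Clustering (MCL) then alternates:

1. **expansion** — raise the column-stochastic flow matrix to the power
   `expansion` (default 2), simulating longer random walks;
2. **inflation** — Hadamard power with exponent `inflation` (default 3.0),
   then prune entries below `prune_threshold` (1e-5; each column's maximum is
   always kept) and renormalize columns,

until the largest entry change is below `tol` (1e-6) or `max_iter` (200)
iterations, whichever first (non-convergence returns best-effort clusters with
a warning flag).  Self-loops with weight equal to each node's maximum
incident edge (1 for isolated nodes) are added before the first
normalization, the standard damping of the even/odd walk oscillation.  The
procedure contains no randomness: identical input gives identical clusters on
any platform.

Clusters are read from the converged matrix's attractors (nodes with positive
diagonal flow); attractor rows with overlapping support are merged, every
node joins the cluster whose attractor value on its column is largest (ties:
lowest cluster index), and a node reached by no attractor — not observed in
practice — falls back to a singleton.  Larger inflation gives more, smaller
clusters; per-chromosome runs equal a genome-wide run because the graph is
block-diagonal across chromosomes.

Within each cluster, bins are split into maximal contiguous runs; the first
and last bin of each run are **boundary** bins, the rest **interior**.  A
cluster is *eligible* for enrichment analysis only if it has at least one
interior bin, so every eligible cluster contributes both test and control
material; a cluster whose bins form more than one run is flagged *distal*.

## Validation statistics

**Within vs across fold.**  Over all unordered pairs of clustered bins on the
same chromosome (zero-count pairs included), the fold is the mean per-pair
count within clusters divided by the mean across clusters.  The p-value is a
one-sided rank-sum test; for tiny samples (total <= 12) it is computed by
exact enumeration of group assignments, since ties distort the normal
approximation there.

**Distance-preserving null.**  Each replicate redistributes, for every bin
distance t, exactly the observed total count at t uniformly at random over
the `lc - t` pairs at that distance (one multinomial draw per distance).
Per-distance totals are conserved exactly by construction, so the null keeps
the decay profile and the coverage while destroying positional structure.
The observed fold is compared with the replicate folds' distribution.  Note
the null folds themselves sit well above 1: within-cluster pairs are
short-range pairs, which carry high totals under any distance-preserving
scheme.  What is informative is the observed fold's exceedance of the null
distribution, not its distance from 1.

**Boundary enrichment.**  Features (peaks by midpoint, genes by TSS) are
assigned to bins; with k features in boundary bins and m in interior bins of
eligible clusters, fold = (k / #boundary bins) / (m / #interior bins) and the
p-value is the exact one-sided binomial tail `P(X >= k)` with
`X ~ Bin(k + m, #boundary / (#boundary + #interior))`.  Expression tiers
(top 25% / middle 50% / bottom 25% by rank, outer tiers of `round(0.25 n)`
genes, stable sort) are tested per tier.  Panels of results get
Benjamini-Hochberg adjustment by default (Bonferroni optional).  The binomial
test on discrete counts is conservative, so its null p-values are
super-uniform rather than uniform.

**Two-condition dynamics.**  Adjacent-bin pairs clustered in condition A
(category Same or Diff by shared cluster membership) are cross-tabulated
against their category in B, where Minus means at least one bin is
minus-state, gap or unclustered in B (an isolated plus-state bin counts as a
non-participant).  A boundary bin of A is *common* if also a boundary in B,
otherwise A-specific.  Cluster similarity at a bin clustered in both
conditions is the Jaccard index of the two containing clusters' bin sets;
bins are ranked by an externally supplied per-bin differential-expression
proportion and mean Jaccard is compared between the top and bottom ranked
fractions.  Percentile grouping ranks R genome-wide over non-gap bins
(average ranks for ties, percentiles in (0, 100], ranges taken as
half-open `(lo, hi]`); the binomial background for gene-set enrichment in a
bin group uses all non-gap bins.

## Synthetic data generator

The generator plants exactly the structure the pipeline is built to detect:

* alternating open/closed blocks tiling a chromosome; block lengths are
  Poisson with mean 20 bins (open) and a closed mean set so the expected open
  fraction is 0.4, matching a ~40/60 two-state split;
* a cluster tiling of each open block with sizes `4 + Poisson(3)` (mean 7
  bins).  The 4-bin minimum is a resolution floor: sub-400 kb domains are not
  representable at 100 kb binning, and planting them would make their bins
  genuinely short-range-depleted relative to the distance mean — a property
  of the fixture, not of the method;
* Poisson counts with expectation `A * t^-alpha` (A = 20 expected contacts at
  adjacent bins, alpha = 1), multiplied by `s_open` = 5 for open-open pairs
  within a `w` = 10-bin window and by `w_in` = 4 for same-cluster pairs;
  self-pairs are zero;
* peaks and genes per bin as Poisson with class rates (boundary 2.0,
  interior 1.0, closed 0.2 per bin) and lognormal expression whose log-mean
  is higher at boundaries (2.0) than interiors (1.0) and closed bins (0.0),
  so highly expressed genes concentrate at planted boundaries;
* a second condition derived by re-drawing the cluster partition (and
  optionally flipping the state) in a chosen fraction of blocks, leaving the
  rest bit-identical.

Everything is reproducible under a seed, and the generator writes its output
in the same text formats the parsers read, so fixtures exercise the real I/O
path.  What the generator does **not** emulate: restriction-fragment bias,
copy-number variation, translocations, overdispersion beyond Poisson,
inter-chromosomal contacts, and compartment-scale checkerboard correlation
structure.  Passing recovery tests therefore show that the estimators invert
the generator's model at realistic signal-to-noise, not that real genomes
meet that model.

## Problem sizes and numerical choices

Tests and the acceptance script run single synthetic chromosomes of
400-2,000 bins, 200-replicate null ensembles, and 500-seed calibration loops
— sizes at which every planted quantity is measurable with comfortable
margins while a full run stays in seconds.  Tolerances: the normalization
invariant holds to 1e-9 (it is a single division); MCL convergence 1e-6 with
pruning 1e-5; determinism is exact (no randomness outside seeded generators).
Degenerate inputs are errors, not silent results: empty comparable-bin sets,
all-equal expression, missing across-cluster pairs, and unclustered bins in
Jaccard queries all raise with a message.

## Known limitations

* The state call at open/closed block edges is intrinsically ambiguous: a bin
  whose window straddles a block edge has a short-range mean near 1, and the
  residual misclassification in recovery tests sits there.
* `as_printed` mode cannot call the last `d+1` bins of a chromosome;
  `symmetric` mode can, at the cost of deviating from the one-sided long-range
  definition.
* Boundary width is fixed at one bin per run end; real insulator regions may
  be wider than 100 kb or fall between bins.
* Enrichment assigns each peak to a single bin by midpoint; peaks spanning a
  bin edge are not split.
* The within/across fold's magnitude depends on the distance composition of
  within- and across-cluster pairs; compare it against the distance-preserving
  null, not across datasets.
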