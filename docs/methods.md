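# Methods

## Matrix construction

The genome (a chrom.sizes listing) is tiled into non-overlapping windows of
a fixed length *L* (defaults: 100 kbp, with 10 kbp as the fine-grained
alternative). Every chromosome contributes ⌈length/L⌉ bins; trailing partial
bins are kept — dropping them would discard signal and a shorter bin does
not bias an average. Intervals are 0-based half-open internally; allc-style
input positions are 1-based and shifted on read.

For cell *i* and region *j* with *k* ≥ 1 captured sites, the matrix entry is
the unweighted mean of the per-site ratios mc/total (each site weight 1).
With binary single-read calls — the typical single-cell case — this equals
the read-weighted ratio Σmc/Σtotal, which is available as a config switch
(`weighted_mean`) for multi-read data. Regions with *k* = 0 are masked (NA).
No minimum-site threshold is applied by default (`min_sites=1`); the mask
marks exactly the zero-site entries, so an observed 0 (all sites
unmethylated) is never conflated with missingness. Strand is parsed but
never used for aggregation; calls on opposite strands of a CpG are kept as
separate sites.

Regions masked in *every* cell carry no statistic for the mean/median
strategies and are removed by an explicit, idempotent drop step before
imputation; imputing with a surviving all-missing column is an error, not a
silent fill.

## Imputation strategies

All four strategies are single-pass: the column statistics (mean, median)
use only *observed* entries, never previously imputed ones, and observed
entries pass through bit-identically. The even-count median is the mean of
the two central order statistics. Because every observed value lies in
[0, 1], all four fills do too, and for each missing entry
`zeros ≤ medians ≤ ones` holds elementwise.

Why the median: in CG data the observed distribution of a DMR-containing
column is a two-component mixture — a large high-methylation mode and a
minority low mode from the hypo-methylated cell types. Whenever the low
fraction is below one half, the column median lies inside the high
component, while the mean is pulled to
(1−f)·μ_high + f·μ_low. The fill error a strategy adds to a cell whose
entry is missing is proportional to (fill − true level)²; for the majority
of cells the true level is near the high mode, so the median adds less
noise. In CH context the baseline is near zero, the median tracks it, and a
constant fill of 1 adds catastrophic noise — these are exactly the
behaviours the benchmark quantifies.

## Embedding and clustering

PCA to 50 components (clipped to min(n−1, R)) with a full deterministic SVD;
no feature scaling or per-cell normalisation precedes it since all entries
share the [0, 1] scale. Component signs are canonicalised by making each
axis's largest-magnitude loading positive. The neighbour graph connects each
cell to its 15 nearest Euclidean neighbours, symmetrized by union with unit
weights; distance ties break toward the lower cell index so the graph is
reproducible. Communities come from igraph's Louvain (multilevel) algorithm
at resolution 1.0 with a seeded RNG. A native modularity evaluator —
independent of igraph — backs the optimiser's oracle tests. These defaults
(50 / 15 / 1.0) are the de-facto standard of the single-cell workflow family
this package follows and are all exposed as configuration.

## Agreement metrics

ARI (Hubert–Arabie), NMI, AMI and the Fowlkes–Mallows index are computed
natively from one shared contingency table, with natural logarithms and the
0·log 0 = 0 convention. AMI's expected mutual information is the exact
finite hypergeometric sum over feasible joint counts, not a sampling
approximation. NMI and AMI normalise by the arithmetic mean of the two
entropies by default; geometric/min/max are available
(`average_method`). Degenerate conventions: two single-cluster partitions
are identical, hence score 1; a single-cluster partition against a split one
has zero mutual information, hence NMI 0; FMI is 0 when a partition has no
co-clustered pair. Values are clamped at 1.0 against ~1e-16 float overshoot.
Tests verify all four against brute-force pair enumeration, explicit entropy
sums, an exhaustive permutation average for the expected MI, and
scikit-learn's implementations as an independent cross-check.

## The simulator

Real scDNAm data are emulated by a Beta-Bernoulli model with Poisson site
capture, on one synthetic chromosome of G windows (multi-chromosome adds
bookkeeping but no statistical content; the binning code is
multi-chromosome-tested separately):

- **Propensities.** Each non-DMR region draws one methylation propensity
  from the context baseline, shared by all cell types: Beta(8, 2) in CG mode
  (mean 0.8 — the high vertebrate CG baseline) or Beta(0.4, 12) in CH mode
  (mean ≈ 0.03 — the near-absent CH baseline). A fraction `dmr_fraction`
  (default 0.1) of regions are DMRs: the affected cell types (1 per DMR by
  default, sampled uniformly) draw from Beta(1.5, 8) (mean ≈ 0.16) instead.
  Because that mean lies below the CG baseline and above the CH baseline,
  one rule yields hypo-methylated DMRs in CG and hyper-methylated DMRs in
  CH — the latter is deliberate: against a near-zero baseline only a hyper
  state carries signal.
- **Capture.** Sites per (cell, region) ~ Poisson(λ), positions uniform
  without replacement within the region. λ defaults to 8 at 100 kbp and
  scales linearly with window length (0.8 at 10 kbp), so shrinking the
  window mechanically raises the NA rate e^{−λ} from ≈0.03% to ≈45% — one
  mechanism reproduces the coarse-vs-fine-tile missingness contrast.
- **Calls.** Each site is methylated with the cell type's propensity;
  read counts are binary (mc ∈ {0,1}, total = 1), matching single-cell
  capture.
- **Determinism.** The entire dataset is a pure function of `SimConfig`:
  the ground truth and every cell derive their RNG streams from
  `(seed, stream, cell_index)` seed sequences.

Defaults: K = 3 cell types × 60 cells, G = 2000 regions. A composition
perturbation utility subsamples without replacement to target type
proportions (largest feasible total T = min⌊available_t/p_t⌋, each type
contributing ⌊T·p_t⌋, rounded down consistently).

What the simulator does *not* model: genome-wide CpG-density maps (density
variation is subsumed by the Poisson rate; a per-region rate multiplier is
the extension hook), bisulfite conversion errors, doublets, batch effects,
or read-level correlation between neighbouring sites. Passing benchmarks
here therefore demonstrate the *mechanisms* — missingness-driven strategy
differences and the DMR mean/median asymmetry — not performance on any
particular real dataset.

## Benchmark scenarios and problem sizes

The benchmark grid builds the matrix once per (window length, simulation
seed) and shares it across strategies, so within-cell metric differences are
attributable to imputation alone. The shipped scenarios use 180 cells ×
2000 regions and five simulation seeds, a size at which the strategy
orderings are stable while a full grid runs in seconds:

- **CG, 100 kbp (λ = 8).** NA ≈ 0.03%: imputation is immaterial and all
  four strategies recover the 3-type partition exactly — the dense-capture
  control.
- **CG, 10 kbp (λ = 0.8).** NA ≈ 45%: `zeros` collapses (mean ARI ≈ 0.5
  below `medians`), `means`/`medians`/`ones` stay near 1. At this ceiling
  `means` and `medians` differ only by single-cell misassignment noise
  (ARI resolution 1/180 per cell).
- **CH, 100 kbp at λ = 2 (NA ≈ 13.5%).** The CH coverage level is a design
  choice: at the default λ = 8 there is no missingness to impute, and at
  λ = 0.8 the near-zero CH signal (1–2 binary sites per observed region) is
  too sparse for *any* strategy to recover the types — neither regime can
  discriminate strategies. λ = 2 is the moderate-missingness middle where
  the contrast is meaningful; the qualitative outcome (`ones` collapses to
  ARI ≈ 0.02 while the other three exceed 0.85) is stable across the whole
  regime with non-negligible NA.

Reports are emitted as JSON + TSV with deterministic ordering and float
formatting, so a rerun of the same config is byte-identical. Aggregates over
a grid with failed cells are refused rather than silently computed.

## Numerical and degenerate-input conventions

- Matrix round-trip uses Python float `repr` (shortest exact form), so
  write∘read is the identity on values, mask, coordinates and ids.
- A matrix with 0 cells is valid everywhere it can be (writing, binning);
  PCA requires n ≥ 2, k-NN requires k < n, Louvain requires a non-empty
  graph.
- Poisson site counts are capped at the region length (sampling without
  replacement cannot exceed it); the cap is logged and unreachable under
  realistic parameters.
- `contingency` aligns partitions by cell id, not by row order, and reports
  the symmetric difference on mismatch.
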