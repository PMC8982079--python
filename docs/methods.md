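# Methods

`stereopipe` re-implements, at desk scale, the computational chain of a
sub-cellular spatial transcriptomics (Stereo-seq) experiment: raw paired
reads are demultiplexed against a coordinate-identity (CID) whitelist,
quantified into a native-resolution count matrix, aggregated into working
bins, and analysed for spatially variable genes, gene modules, functional
regions, cell-type composition and regulon activity.  A built-in simulator
provides every input together with exact ground truth, so the whole chain
is testable without external data.

## The measurement model

A Stereo-seq chip is a lattice of DNA nanoball capture spots at 500 nm
center-to-center pitch (bin1).  Each spot carries a unique 25-base CID;
captured transcripts receive the spot's CID and a random 10-base UMI.
Read1 is `CID(25) + UMI(10)`, read2 is cDNA.  Processing follows the
standard chain:

1. **Demultiplexing** — exact CID hash lookup, then 1-mismatch recovery
   by probing all 75 single-base variants of the query against the same
   hash.  A query matching two whitelist entries at distance 1 is
   *ambiguous* and rejected (assigning it arbitrarily would leak counts
   across positions).  `N` counts as a mismatch.  Reads shorter than 35
   bases are tallied separately (`too_short`) so ratios stay well defined.
2. **UMI filter** — a UMI fails if it contains any `N` or at least two
   bases below Phred 10 (strict; Phred+33).
3. **Alignment** — a toy exact-substring aligner over a small panel of
   unspliced gene sequences, both strands: unique placement scores MAPQ
   255, multi-gene placement MAPQ 3, and the retained disposal rule is
   MAPQ < 10.  For real data, externally produced alignment tables can be
   fed to the counting step instead.
4. **Counting** — UMIs collapse by exact string identity per (spot, gene);
   no edit-distance merging.  The count at a key is the number of
   distinct UMIs.
5. **Binning** — half-open floor-division squares, 0-based; bin50
   (50 x 500 nm = 25 um) is the conventional working unit at full scale.
   Totals are conserved exactly; partial edge bins are kept and flagged
   with their true spot capacity.

Decision order matters for bookkeeping: parse → CID → UMI, with each read
attributed to the first rule it fails, so the rejection counters partition
the input exactly.

## Spatial statistics

Counts are normalized per bin to the median bin total and log1p
transformed before any spatial statistic.

**Spatially variable genes.**  The upstream workflow this package models
delegates SVG detection to external autocorrelation software; here the
statistic is Moran's I on a row-normalized k-nearest-neighbor graph
(k = 15 by default, Euclidean distances on bin centers, distance ties
broken lexicographically), with an explicit permutation null: one shared
set of `n_perm` bin relabelings across genes, one-sided p-values with +1
smoothing, Benjamini–Hochberg q-values.  With row-normalized weights
`I = Σ w_ij z_i z_j / Σ z_i²` equals the classical n/S0-scaled form, and
the permutation-null mean is −1/(n−1).  Constant genes are flagged
untestable rather than dropped silently.

**Modules.**  Significant genes are smoothed one graph step
(`(x + Wx)/2`), correlated pairwise (Pearson), and clustered by
average linkage on `1 − r`; the tree is cut at correlation 0.3 by default
or to a fixed module count.  Modules below the minimum size (2) go to an
"unassigned" pool.  A module score is the mean per-gene z-score across
members, re-standardized per column.

**Regions.**  k-means (k-means++ initialization, 10 restarts, seeded) on
the bins × modules score matrix; labels are renumbered by descending
cluster size, and per-cluster percentages plus a k × k Pearson correlation
of cluster-mean profiles summarize the partition.  At full scale k = 10 is
the conventional setting; the bundled synthetic section plants four
regions, so its default configuration clusters at k = 4 and scores the
labels against the planted truth (adjusted Rand index).

**Differential expression and gradients.**  Region pairs are compared per
gene with a Wilcoxon rank-sum test on normalized expression (BH-corrected)
and a log2 fold change with pseudocount 1 on cluster means; positive means
higher in the first cluster.  Monotone proximal→distal trends are scored
by Spearman correlation of expression against one lattice axis with a
permutation p-value (two-sided), computed in closed form on ranks.

## Cell-type deconvolution

Counts in a bin are modelled as `c_g ~ Poisson(N · Σ_t w_t θ_gt)` where
θ columns are reference expression probabilities and `w` lies on the
simplex.  Types supported by fewer than 20 reference cells are removed up
front (strict).  The MLE is found by multiplicative EM,

    w_t ← w_t · Σ_g [c_g θ_gt / Σ_u w_u θ_gu] / Σ_g c_g ,

initialized uniform, stopped at `max_iter` (500) or log-likelihood gain
below `tol` (1e-8); the objective is concave so the optimum is global, and
the per-iteration log-likelihood trace is available for monotonicity
checks.  Bins may hold several types, capped at `max_types` (4) by greedy
backward elimination: while more types than the cap remain, the type
whose removal costs the least log-likelihood is dropped and the model is
refit.  The cap is the sole driver of elimination; an elimination costing
more than 1% of |log-likelihood| is logged as a strained fit rather than
used as a sparsification rule, because evicting genuinely present
low-weight types at that threshold would bias compositions and would make
an inactive cap differ from the unconstrained fit.  Genes used are the
reference ∩ section intersection minus mitochondrial (`mt-`) genes.
Summaries: type × type Pearson correlation of weight maps, per-bin
composition percentages, and a per-type "relative cell number" defined as
summed weights normalized to percent (sum-then-normalize; a mean-based
aggregation would weight sparse bins equally with dense ones).

This estimator deliberately replaces the full hierarchical model of
dedicated deconvolution tools (platform effects, per-gene overdispersion)
with the plain Poisson mixture: the behaviors required of this stage are
the < 20-cell pre-filter, multi-type bins, and the composition summaries.

## Regulon activity

Regulons (a TF plus its target set, labelled `Tf(+)`) are inputs; network
inference is out of scope.  Per bin, all genes are ranked by raw
expression, descending, with ties broken by a seeded uniform random order
per bin (alphabetical tie-breaking would systematically favour regulons
with early-sorting gene names; the seed is recorded in the output).  With
window `W = ceil(top_fraction · G)` (top_fraction = 0.05), the activity is
the area under the step recovery curve of target hits over ranks 1..W,
divided by the maximal area achievable if all `m` measured targets were
packed at the top (`Σ_{r≤W} min(r, m)`), hence scores lie in [0, 1]; the
null mean for a random m-set is `m/G` exactly.  A regulon with no measured
target yields NaN, and pairwise Pearson correlations of the activity maps
across bins summarize spatial co-regulation (constant maps give undefined
correlations, left blank).

## The synthetic experiment

The simulator is the package's study design, not a test fixture:

* **Chip** — default 200 × 200 bin1 spots (100 µm square).  CIDs are
  rejection-sampled to pairwise Hamming distance ≥ 3 (checked by a
  9/8/8-segment pigeonhole index), which makes 1-mismatch decoding exact
  and gives demultiplexing tests crisp truth.  An explicit
  `allow_close_codes` mode plants distance-2 pairs and records, for each,
  the midpoint probe at distance 1 from both — the only way ambiguity can
  occur, and therefore the mechanism for injecting ambiguous reads.
* **Tissue architecture** — four regions with canonical mouse-lung
  markers: a bronchiole ring (Clara-cell markers Scgb1a1, Scgb3a2,
  Cyp2f2, Hp), an alveolar background (AT2: Sftpc, Ager, Car4; fibroblast:
  Dcn, Cdk8), a vessel stripe (Acta2, Myh6, Myl7) and three immune foci
  (S100a8, S100a9), plus five `mt-` genes for the mito QC map and four
  distal-gradient genes (Malat1, Jarid2, Lars2, Il31ra) whose rate ramps
  linearly along +y from 0.02 to 0.30 per spot.  Each region's per-gene
  rate is `depth · Θ w_region` with Θ the cell-type signature matrix and
  `depth = 2` transcripts per spot — so bin counts are exactly the Poisson
  mixture the deconvolution assumes, and the per-bin area-average of
  region weights is the deconvolution truth.  60 genes total, including
  two never-expressed decoys sharing an internal 80-bp block (the source
  of genuinely multi-mapping reads) and 35 low-level fillers.
* **Reads** — per molecule, 2 duplicate reads by default (exercising UMI
  collapse); UMIs uniform over 4^10 but kept distinct within each
  (gene, x, y) key so the error-free channel reproduces truth counts
  exactly (real UMI collisions are a < 1e-5 effect at these depths).
  Base qualities are drawn from a 5-level distribution giving ≈ 90% Q30.
  At most one error is injected per read via a single categorical draw —
  invalid CID (replaced by a verified off-whitelist code), ambiguous CID
  (a close-pair probe), two-base Q2 UMI damage, UMI `N`, an alien cDNA, or
  a decoy-block cDNA — so demultiplexer counters are comparable
  flag-for-flag with provenance.  The noisy default channel injects 1%
  invalid, 1% ambiguous, 2% low-quality-UMI, 0.5% UMI-N, 2% unmappable
  and 1% multi-mapping reads.

What the simulator does *not* emulate: optics and permeabilization
efficiency, transcript splice structure (the toy aligner is exact-match on
unspliced sequences), sequencing indels, UMI collisions and PCR-error UMI
families, per-gene overdispersion beyond Poisson, and platform effects
between the reference and the section.  Passing tests therefore certify
the pipeline's logic and calibration under the stated generative model,
not robustness to those real-data effects.

## QC metrics

Q30 is the fraction of bases at Phred ≥ 30, reported per segment (CID,
UMI, cDNA).  The barcode mapping ratio counts reads with a valid,
unambiguous CID over all read pairs; the reads mapping ratio counts mapped
reads over reads entering alignment (both definitions are printed in the
report).  Between-section reproducibility R² is the squared Pearson
correlation of log1p per-gene pseudobulk totals over the union gene set —
the pseudobulk definition is this package's documented choice, as the
level at which such replicate R² values are computed is conventionally
left unstated.

## Numerical choices and problem sizes

Default problem sizes keep the full suite at desk scale: the 200 × 200
chip yields ≈ 105k molecules / 210k read pairs at depth 2, and analyses
run at bin 10 (400 bins, median ≈ 260 counts per bin) — the chip is only
4 bin50 squares wide, so bin50 output is produced for format fidelity
while bin 10 is the synthetic working resolution.  Permutation tests use
n_perm = 500 and a shared permutation set across genes.  EM uses a 1e-300
floor inside logs against underflow; k-means ties and KNN distance ties
are broken deterministically; GEM/MTX writers sort rows so reruns are
byte-identical.  All randomness flows through explicit integer seeds.

## Known limitations

* The toy aligner is exact-match only; a single cDNA base error makes a
  read unmappable rather than mismatched-but-aligned.
* Ambiguous-CID handling on real chips whose code sets were not designed
  for distance ≥ 3 may reject more reads than vendor software that
  resolves ambiguity by quality or abundance; the rejection policy is
  deliberate and documented.
* The deconvolution assumes the reference and section share expression
  scale up to a global factor per bin; systematic platform effects are
  not modelled.
* Regulon activity uses a fixed top-rank window; no binarization or
  per-regulon thresholding is provided.
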