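# stereopipe

A desk-scale, fully testable re-implementation of the computational chain
behind sub-cellular spatial transcriptomics (Stereo-seq) of mouse lung:
from raw paired reads to spatial domains, cell-type composition and
regulon activity maps.

Stereo-seq captures mRNA on a lattice of 220 nm spots at 500 nm pitch,
each spot tagged by a unique 25-base coordinate identity (CID) barcode.
`stereopipe` implements every downstream step of that measurement:

* **demux** — read1 parsing (`CID(25) + UMI(10)`), whitelist matching with
  1-base-mismatch tolerance (index-backed, ambiguity rejected), and the
  UMI quality rule (no `N`, fewer than two bases with Phred < 10);
* **quantify** — a toy exact-substring aligner over a gene panel (both
  strands; unique hit → MAPQ 255, multi-gene → MAPQ 3), the `MAPQ < 10`
  disposal rule, and distinct-UMI counting per (spot, gene) into the raw
  bin1 matrix;
* **binning** — aggregation of bin1 into bin *N* squares
  (bin50 = 50 × 500 nm = 25 µm), count-conserving, with bin centers
  assigned;
* **qc** — per-segment Q30, barcode and reads mapping ratios, per-bin UMI
  and mitochondrial-fraction maps, and between-section reproducibility
  R² on log1p per-gene pseudobulk;
* **spatial** — spatially variable genes by Moran's I,
  `I = Σ w_ij z_i z_j / Σ z_i²` on a row-normalized KNN graph with a
  seeded permutation null and BH correction; gene modules by
  average-linkage clustering of smoothed-expression correlations; per-bin
  module scores; k-means functional regions with cluster percentages and
  correlations; rank-sum DEG between regions; proximal→distal gradient
  tests (Spearman with permutation p);
* **deconv** — per-bin cell-type composition under a Poisson mixture,
  `c_g ~ Poisson(N Σ_t w_t θ_gt)`, fit by multiplicative EM on the
  simplex (concave objective, monotone log-likelihood), with the strict
  < 20-cell reference pre-filter and a per-bin cap on the number of types;
* **regulons** — AUCell-style per-bin activity for supplied TF→target
  sets: area under the top-5%-rank recovery curve, normalized to [0, 1],
  with seeded tie-breaking and spatial correlation of activity maps;
* **synthetic** — a first-class simulator that generates the chip (CIDs at
  pairwise Hamming distance ≥ 3), a planted lung-like section (bronchiole
  ring, alveolar background, vessel stripe, immune foci, distal-gradient
  genes), and UMI-tagged paired reads with configurable error injection —
  all with exact per-read and per-bin ground truth.

Intended users: developers of spatial-omics pipelines who need a small,
deterministic, truth-bearing testbed, and readers who want each processing
rule of this class of experiment stated precisely and executably.

## Worked example

Run the full pipeline on the built-in synthetic section (200 × 200-spot
chip, noisy read channel):

```bash
stereopipe run --out run1 --seed 0
```

which prints the run's headline metrics:

```json
{
  "barcode_mapping_ratio": 0.98028139695516,
  "deconv_weight_rmse": 0.028050847694844273,
  "reads_mapping_ratio": 0.9790513657736576,
  "region_ari": 0.9167542719476203
}
```

Reading these numbers: of 211,374 simulated read pairs, 98.0% carried a
valid, unambiguous CID (the simulator injected 1% invalid and 1%
ambiguous barcodes: the demultiplexer's counters — 2,072 invalid, 2,096
ambiguous, 5,379 low-quality-UMI — match the injected error flags
read-for-read); 97.9% of accepted reads aligned to the gene panel; the
per-bin cell-type weights recovered by the EM deconvolution sit within
RMSE 0.028 of the planted composition; and k-means on the module scores
reproduces the four planted tissue regions at adjusted Rand index 0.917.
The run directory holds every intermediate artifact: the whitelist,
FASTQs, `bin1.gem` / `bin50.gem` / `bin10.gem` matrices (bin50 is 25 µm;
the analyses run at bin 10 on this small chip), the QC report, SVG /
module / region / DEG tables, deconvolution weights and regulon
activities, plus `manifest.json` recording all parameters and seeds.
On this section the module step finds 5 spatial gene modules (the four
region marker groups plus the distal-gradient group), the four region
clusters cover 74.8 / 15.0 / 7.0 / 3.2 percent of bins, and the relative
cell numbers come out AT2 49.8%, alveolar fibroblast 32.7%, smooth muscle
12.0%, Clara 4.0%, neutrophil 1.5% — i.e. the alveolar types dominate,
as planted.

The same stages are available individually (`stereopipe simulate`,
`demux`, `count`, `bin`, `qc`, `qc-compare`, `svg`, `modules`, `cluster`,
`deg`, `deconvolve`, `regulon-activity`) and as library functions:

```python
from stereopipe import simulate_section, demux_stream, count_pipeline

section = simulate_section(seed=0)
result = demux_stream(section.reads.read1, section.reads.read2, section.layout)
bin1, ratios = count_pipeline(result.records, section.gene_panel, 200, 200)
print(result.barcode_mapping_ratio, ratios["reads_mapping_ratio"])
```

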