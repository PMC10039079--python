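# Methods

This note documents the models, algorithms and numerical choices behind
`barnyardqc`, and what the bundled simulator does and does not emulate.

## The generative model of a barnyard experiment

The simulator (`barnyardqc.simulate`) models a bead-based capture
experiment in which each cell is tethered to one barcoded bead, complexes
are immobilized and lysed, and each bead captures mostly its own cell's
mRNA plus a small amount of pooled lysate from elsewhere in the sample.

Per experiment:

* **Genes.** `genes_per_species` genes per species (default 500), of which
  `mito_fraction` (default 3%) are flagged mitochondrial. Each species gets
  an expression profile drawn from a symmetric Dirichlet with concentration
  0.05, giving the heavy-tailed expression typical of real transcriptomes.
* **Complexes.** `n_cells_per_species` primary cells per species (default
  2,500 + 2,500, an equal 1:1 human/mouse mixture of 5,000 complexes, the
  standard design for characterizing multiplet rates). With probability
  `doublet_prob` (default 0.06) a complex carries a second cell whose
  species is uniform over the species list — so in an equal two-species
  design half of all doublets are hetero-species.
* **Transcripts.** Each barcode captures `T ~ NB(mean 5000, dispersion 2)`
  transcripts (dispersion = gamma shape; variance = mean + mean²/dispersion).
  A fraction `ambient_rate` (default 0.01) of them comes from the ambient
  pool; the rest from the barcode's own cell(s). A doublet's own transcripts
  are split between its two member cells with equal weight (binomial 1/2).
  The ambient pool's species composition is proportional to total cellular
  transcript mass per species — the simplest mass-action picture of lysate
  diffusing between neighbouring complexes.
* **Empty beads.** `n_empty_beads` barcodes capture only ambient material,
  Poisson(`empty_bead_mean`, default 20) transcripts each. The default is 0
  empty beads: the core species statistics are defined on cell-associated
  barcodes, and tests of cell calling construct their own background
  explicitly.
* **Reads.** At read level every transcript gets a UMI drawn uniformly over
  4^12 (collisions allowed — they are what deduplication loses, and the
  birthday expectation n(n−1)/2 · 4⁻¹² makes the loss testable) and is
  emitted as `max(1, Poisson(lambda))` duplicate reads. FASTQ rendering puts
  the 16-base barcode and 12-base UMI at the start of a 30-base R1 and the
  first 70 bases of the gene's catalog transcript in R2, with constant 'I'
  qualities. The default substitution error rate is 0.

Everything is driven by one integer seed through `numpy`'s `default_rng`;
identical configurations produce byte-identical outputs.

**What the simulator does not emulate:** real transcript sequences (the
catalog is random 500-mers, so gene assignment by exact 31-mer prefix lookup
is a stand-in for exon-aware alignment, not a model of it), sequencing
quality variation, barcode synthesis errors, chimeric PCR artifacts,
cell-type structure within a species, and homo-species doublets' elevated
transcript totals (a doublet draws one NB total, matching the equal-weight
mixture model). Consequently, passing tests demonstrate the *pipeline
arithmetic* — calling, deduplication, purity, rates — under a controlled
model; they do not certify performance on real alignment or barcode-error
regimes.

## Cell calling

The knee detector works on the cumulative count curve. Barcodes are sorted
by descending count (ties by barcode string, so results are deterministic);
counts are moving-average smoothed over a 15-rank window; the cumulative sum
is scaled to [0, 1] on both axes; and the knee is the point with maximum
perpendicular distance to the chord joining the curve's endpoints, ties
broken toward smaller rank. Because the cumulative curve's slope drops
abruptly where cells give way to background, the maximum-distance point sits
at that boundary. An earlier formulation — maximum distance to chord on the
log-log rank curve itself — was measured on two-plateau benchmarks
(5,000 Poisson(1000) cells over 100,000 Poisson(10) empties) to call only
~97.7% of cells: on a point curve the maximum-distance location is where the
plateau tail's slope matches the chord slope, which is systematically inside
the plateau. The cumulative formulation calls ≥ 99% with ≤ 0.01% background
contamination on the same benchmarks, and is the package's default and only
knee.

Degenerate inputs: fewer than 100 barcodes with count ≥ 1 is an error; a
curve that is straight on log-log axes to within 10⁻⁶ (constant counts, or
an exact power law — a scale-free background with no cell population) raises
a no-knee error that points at `manual_threshold`. The calling threshold is
the unsmoothed count at the knee rank; all barcodes strictly above it are
called, plus ties up to the knee rank.

The rank curve uses raw (pre-deduplication) read counts by default, since
calling precedes deduplication in the pipeline order; any count vector can
be passed.

## Quantification choices

* Deduplication key is the exact (barcode, UMI, gene) string triple. No
  UMI error-collapsing (e.g. directional networks) is attempted; with the
  simulator's error-free UMIs the only loss channel is true collisions.
* Unassigned reads count toward a barcode's raw-read depth but never toward
  transcripts: depth is quoted as *raw reads per cell*.
* Downsampling is one binomial thinning of the whole read stream, not
  per-cell equalization — targets are averages per analyzed cell.
* PCR-tube splitting assigns *barcodes* (beads) to tubes uniformly at
  random; physically the beads are what gets split, so tubes are disjoint
  and exactly partition the matrix.

## Species purity and multiplet rates

Purity is `1 − 2·min(a,b)/(a+b)`. Threshold comparisons are done in exact
integer arithmetic (`20·(a+b−2·min) ≥ 19·(a+b)` etc.) so the boundary cases
behave as specified: purity exactly 95% **is** assigned; purity exactly 2/3
is **not** a multiplet. The three classes (species A, species B, undefined)
and the hetero-multiplet rate all share one denominator, the analyzed
barcodes (barcodes with ≥ 1 transcript); zero-transcript barcodes are
excluded and counted. The ×2 extrapolation from hetero-species to total
multiplet rate is only valid for equal species proportions; for unequal
designs the summary reports the hetero rate alone with an explanatory note
rather than inventing a correction.

## Post-processing

Filters run in a fixed order: genes in fewer than `min_cells_per_gene`
cells (default 3) are dropped first; then cells with fewer than
`min_genes_per_cell` genes (default 200), counted on the remaining genes;
then cells whose mitochondrial rate exceeds `max_mito_rate` (default 20%),
computed on the remaining genes. One pass of each rule; the report carries
per-rule drop counts. Re-filtering an already-filtered matrix is a no-op in
ordinary regimes, but because cell removal can in principle push a gene
back under the gene threshold, strict idempotence is a property of the data,
not an iteration-to-fixpoint guarantee.

Normalization is `log2(10000·X + 1)` with X the *fraction* of the cell's
transcripts on the gene, i.e. counts-per-ten-thousand on a log2 scale; with
X read as a 0–100 percentage the 10,000 multiplier would lose that meaning.
Zeros map to zeros, preserving sparsity; values are monotone in X and
invariant to the cell's depth. Cells with zero transcripts must be filtered
out first (error otherwise). Mitochondrial genes come from the feature
table's flag; when building feature tables from plain gene lists, the
conventional "MT-"/"mt-" prefix is the expected source of that flag.

HVG selection, PCA, embedding, clustering and differential expression are
deliberately out of scope: the filtered/normalized matrix exports cleanly
(MTX, or AnnData via `CountMatrix.to_anndata`) to scanpy/Seurat-style
toolchains that do those steps well.

## Wet-lab estimators

Expected cells in data = complexes × per-tube recovery × tubes sequenced,
with the per-tube recovery capped at 1/n_tubes (12.5% for 8 tubes). Gel
spacing offers two definitions, deliberately both: the cube-root lattice
spacing `(V/n)^(1/3)` (585 µm for 10,000 cells in 2 mL) and the mean
nearest-neighbour distance of a homogeneous Poisson process,
`0.5539·(n/V)^(−1/3)` (324 µm for the same geometry). Neither is privileged;
quoted "average spacing" figures in the field usually sit between them, and
the ratio is the constant 0.5539. Estimates are point values; microscope
counting error is not propagated.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on simulated data:
the species-rate checks use the full 5,000-complex design at count-matrix
level over ten seeds; knee benchmarks use 105,000-barcode curves over ten
seeds; read-level pipeline checks use small configurations (80 cells, 400
empty beads, ~300 transcripts/cell) where every read can be compared to its
generative truth exactly.
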