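# Methods

This note documents the models, numerical choices, and design decisions
behind `recold`, and what the synthetic benchmarks do and do not
demonstrate.

## Alignment and dissimilarity

Pairwise sequence similarity is the maximum Smith–Waterman local
alignment score under affine gaps, computed by a quadratic Gotoh
dynamic program over the 20-letter amino-acid alphabet. The inner loop
is JIT-compiled with numba; the compiled kernel is required to be
score-identical to the plain dynamic program (the test suite checks it
against an independently written pure-Python DP, exhaustively for short
sequences and on thousands of random pairs).

Gap convention: a gap of length $L$ costs
$\text{open} + (L-1)\cdot\text{extend}$ (defaults 10 and 1), the
convention of the widely used striped-SW implementations. The
alternative $\text{open} + L\cdot\text{extend}$ convention is available
via `AlignmentParams(gap_convention="open-plus-extend")`.

Substitution matrices are the standard NCBI tables (PAM 30/100/120/
160/250, BLOSUM 45/50/62/80/100), loaded from biotite's bundled data;
BLOSUM62 is the default, being the de-facto standard for TCR and
peptide work. All ten tables are symmetric with strictly positive
diagonals, which has two consequences used elsewhere: the self
local-alignment optimum is the full gapless self-match (so
$D_{ii}$ is the sum of diagonal scores), and
$0 \le S_{ij} \le 1$ with $S_{ii}=0$ for the length-adjusted
dissimilarity $S_{ij} = 1 - 2D_{ij}/(D_{ii}+D_{jj})$.

## Embedding

All four methods consume the precomputed dissimilarity matrix; none
needs coordinates in sequence space. Embedded coordinates are defined
only up to rigid motion (and method-specific scale), so all downstream
quantities are built from inter-point distances and densities, never
absolute coordinates.

* **MDS** minimizes raw stress $\sum_{i<j} (S_{ij} - \|y_i-y_j\|)^2$
  with SMACOF majorization. SMACOF is implemented in-package (~40
  lines) rather than delegated, because the stress trajectory across
  iterations is part of the method's contract (stress is provably
  non-increasing per Guttman transform, and the tests assert it).
  Defaults: 500 iterations, relative-improvement tolerance 1e-9,
  Gaussian random initialization from the configured seed.
* **ISOMAP** builds a k-nearest-neighbor graph on $S$ (k = 10 by
  default), symmetrized by union to avoid spurious disconnection,
  computes all-pairs shortest-path geodesics (Floyd–Warshall), and then
  applies the same stress minimization to the geodesic matrix. A
  disconnected graph is an error naming the component count.
* **Spectral embedding** (Laplacian eigenmaps) uses the same kNN graph
  with edge weights $e^{-S_{ij}/\bar S}$ ($\bar S$ = mean edge
  dissimilarity; zero-dissimilarity duplicate pairs get weight 1) and
  the symmetric normalized Laplacian. Eigenvector signs are fixed
  deterministically (largest-magnitude entry positive).
* **t-SNE** runs scikit-learn's implementation with
  `metric="precomputed"`: Gaussian kernel with perplexity-calibrated
  per-point bandwidth in the input space (default perplexity 30,
  reduced automatically for small inputs), Student-t kernel in the
  embedded space.

MDS is the pipeline default: it is deterministic given a seed, and
together with t-SNE it spreads points widely enough for stable density
comparison. t-SNE optimizes a non-convex objective; even duplicate
points (zero input dissimilarity) end up merely *near* each other in a
minority of runs rather than strictly mutually nearest — the tests
encode that empirical behavior (mutual nearest neighbors in ≥ 8/10
runs, always within the 3 nearest).

## Density estimation

The shared grid covers every sample's points: per axis,
$[\min x - (\max x - \min x)/10,\ \max x + (\max x - \min x)/10]$ in
400 equal bins (default). Bins are half-open with the final bin
closed, so point-to-bin assignment is deterministic.

The kernel is exponential, $K(r) = e^{-r/h}$, evaluated at bin centers
and normalized discretely so each sample's bin probabilities sum to 1.
This makes the JSD an exact finite sum over bins. Evaluating at
centers rather than integrating over bins is a deliberate
simplification; at 400 bins/axis the difference is far below the
estimation noise.

The bandwidth is selected per sample by 5-fold cross-validated
held-out log-likelihood over a log-spaced ladder spanning
$[10^{-2}, 10]$ times the sample's median nearest-neighbor distance
(ties take the smallest candidate; a global override is available).
Per-sample optimization is used because each sample's PDF is a
separate estimate; a shared bandwidth can be imposed through the
pipeline's `bandwidth` option.

Two evaluation paths exist with matching results: an exact tree-based
path (scikit-learn `KernelDensity`, used for arbitrary point sets) and
an FFT-convolution path for points lying exactly on bin centers
(`BinnedKernel`), which caches the kernel transform and is used by the
bootstrap. Integer point weights are exactly equivalent to duplicating
points (up to float summation order, ≲ 1e-9 relative in bins of
negligible probability).

## Divergence, contributing sequences, significance

The JSD is computed in natural logarithms (range $[0, \ln 2]$; a bits
option divides by $\ln 2$) with the $0\ln 0 = 0$ convention. The
per-bin local JSD is non-negative (log-sum inequality) and sums exactly
to the global value.

**Contributing sequences.** Bins with positive local JSD are ranked
descending and the top `ceil(0.01 × n_positive)` are selected,
including ties at the cutoff; each sample's sequences landing in
selected bins are reported. The 1% budget is computed over
positive-local-JSD bins rather than all bins — with exponential
kernels essentially every bin is positive, so in practice the two
readings coincide at ~1% of the grid.

**Bootstrap.** For each sample, `n_boot` (default 100) replicates draw
n points from the sample's own binned density, re-estimate the density
with the naive bandwidth, and record the JSD between naive and
re-estimated densities. The 99th percentile (linear interpolation
between order statistics — pinned for reproducibility) is the
one-sided 1% threshold; a pair is flagged significant when its naive
JSD exceeds both members' thresholds. Two choices here deserve
explanation:

* *Resample size.* By default the pipeline resamples as many points as
  the naive estimator actually used — the unique-sequence count for
  unweighted KDE, the total read count for count-weighted KDE
  (`bootstrap_n="match"`). A parametric bootstrap must mimic the
  estimator's own sampling process; resampling the (much larger) read
  count under an unweighted KDE produces re-estimates that are less
  noisy than the estimator itself, an anti-conservative null that
  falsely flags exchangeable samples. `"reads"` and `"unique"` are
  available to force either convention.
* *Bin-center resampling.* Resampled points are placed at bin centers
  (no within-bin jitter by default), which allows exact FFT
  re-estimation and makes 100 replicates cost a few seconds on a
  400×400 grid. Within-bin offsets are far below any cross-validated
  bandwidth, and a fixed-bandwidth KDE is well-defined for coincident
  points, so jitter changes nothing statistically; it remains available
  (`jitter=True`).

The bootstrap reuses the naive bandwidth rather than re-optimizing per
replicate — re-optimization would multiply cost ~50-fold and adds
variance from the ladder discretization, not signal.

**Position frequencies.** Contributing sequences of equal length can be
summarized as a position × residue relative-frequency matrix (rows sum
to 1), the numeric form of a sequence logo; mixed-length sets must be
grouped by length first (no multiple alignment is attempted).

## Clustering

Ward linkage is applied to the JSD matrix through the Lance–Williams
recurrence *as-is*. JSD is not a squared Euclidean distance, so Ward's
variance interpretation does not strictly hold; it is used as a
merge-ordering heuristic, with `average` and `complete` linkage as
alternatives. The cophenetic correlation coefficient is reported as a
diagnostic, with the caveat that Ward tends to produce lower values
than average linkage even when its partitions are better — the
bootstrap significance test, not the CCC, is the recommended check.
Dendrograms export as Newick with branch lengths equal to merge-height
differences.

## Synthetic data

The generator emulates the structure this method is designed to
detect. A motif family is a CDR3-like template (cysteine-led prefix,
F/W-containing suffix, lengths 11–16) with two variable core positions,
each substituted with probability 0.5 per draw — so generated
sequences sit within 1–2 substitutions of the consensus, the
neighborhood structure characteristic of motif-sharing CDR3 groups, and
each family spans a sequence space of 400 variants. Families of
different lengths occupy provably disjoint sequence spaces. Samples are
mixtures over families with a specified number of unique sequences
(drawn by rejection until distinct) and clone counts from a truncated
discrete power law (exponent 2.5), giving the count-weighted KDE path
heavy-tailed input.

Two canonical designs drive the benchmarks:

* `planted_difference_design` — a planted sample drawing an
  `exclusivity` fraction (default 1) of its sequences from a family
  absent from the reference sample(s), plus optional exchangeable
  references sharing the base family.
* `hierarchy_design` — eight samples over three binary factors of
  decreasing planted effect (0.55 of mixture mass moved between
  genotype families, 0.25 onto a cell-type family, 0.10 onto a
  donor-site family), inducing the divergence ordering
  site < cell type < genotype.

What passing synthetic benchmarks show: the pipeline separates planted
from exchangeable pairs at the prescribed bootstrap threshold, orders
and recovers a planted hierarchy, and localizes divergence to the
correct embedding region. What they do not show: behavior under real
V(D)J generation statistics (no recombination model, no generation
probabilities), sequencing error, PCR amplification bias, or
repertoires whose families overlap in sequence space.

## Known limitations

* **Contributing-sequence recall is bounded by the bandwidth.** The
  top-1% rule selects bins by divergence mass, not by sequence
  occupancy. With the cross-validated bandwidth (typically 3–4 bin
  widths at the benchmark scale of 200 sequences/sample), local-JSD
  mass concentrates in smoothed cluster cores, and peripheral member
  sequences fall outside the 1% bin budget: on the planted-difference
  benchmark the contributing set captures roughly 50–85% of the
  planted family (seed-dependent), and reaches 100% only if the
  bandwidth is forced ~4× below the likelihood optimum. The procedure
  is therefore a *region finder* — it reliably localizes where
  divergence lives and returns the sequences at its core — rather
  than an exhaustive extractor of the divergent sub-repertoire.
* Embedding distortion: a motif family is a Hamming ball, which is not
  isometrically embeddable in 2-D; within-cluster distances correlate
  only moderately (~0.5) with the alignment dissimilarities. All
  conclusions should rest on densities and divergences, not on
  within-cluster geometry.
* JSD values depend on the embedding method and its seed (t-SNE
  especially); the pipeline pins every seed and records effective
  parameters in its run log for exact reproducibility.
* No multiple-testing correction is applied across sample pairs; with
  many samples the 1% per-pair level is nominal.

## Benchmark problem sizes

The shipped tests and the acceptance script run the full pipeline at
200 unique sequences per sample (three samples; union ≈ 500–600
sequences) for the planted-difference experiments, with 100 bootstrap
replicates at the 99th percentile, and 150 unique sequences per sample
for the eight-sample hierarchy — sizes chosen to match the restricted-
repertoire regime the method targets (a few hundred unique CDR3s per
sample) while keeping a complete run in minutes on one CPU.
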