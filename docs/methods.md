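# Methods

This note documents the models implemented in `spotmap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results should know.

## Model and assumptions

**Inputs.**  A single-cell (SC) reference — gene x cell counts with one
type label per cell, types with fewer than `min_cells = 5` cells removed —
and a spatial (ST) dataset — gene x spot counts with one (x, y) coordinate
per spot, treated as continuous Cartesian positions in the input's units.

**Normalization.**  The reference implementation family for this kind of
pipeline normalizes with a regularized negative-binomial model; this
package provides two light-weight stand-ins with the same contract (a
common normalized space across datasets): `log_cp_median`
(`ln(1 + x * m / L)`, m = median library) as the default, and NB Pearson
residuals with fixed dispersion 100, clipped at +/- sqrt(n_columns).  They
reproduce neither the regularized parameter fits nor anchor-based
integration; a user-supplied joint embedding bypasses the built-in
integration entirely.

**Marker specificity.**  `spec_i = (w_i/K) sum_j r_j log2 r_j` on the
normalized per-type means (the layer is configurable; normalized is the
default).  Argmax-type ties break toward the lower type index for
determinism.  The variance filter ("drop genes more than 3 SD above the
mean variance" within the assigned type's cells) is applied to
*trend-relative* variance: each gene's within-type variance is divided by a
running-median trend over genes ordered by mean expression, and a gene is
flagged only when it exceeds the mean + 3 SD of that ratio *and* at least
2x the trend.  Rationale: on any normalization short of fully
variance-stabilizing, raw variance tracks expression level, so an absolute
cutoff would preferentially discard exactly the highly expressed
type-specific genes the score is designed to find; and below 2x the trend
an excess is within chi-square sampling noise of a per-type variance
estimate.  Markers absent from the ST gene universe are dropped before any
downstream use, since the likelihood needs shared genes.

**Likelihood and spatial weighting.**  Likelihoods are computed and kept in
log10 space throughout (no underflow up to >= 1e6 counts per spot); the
multinomial coefficient is dropped as a per-spot constant.  Spot marker
counts use the raw counts layer (the multinomial models counts); cell
probability vectors use the normalized layer with Laplace smoothing 1e-6.
Distances for the weight matrix are Euclidean in the 2D joint embedding —
local structure is what matters here, and the known global-distance
distortion of neighbor-preserving projections is accepted rather than
"improved".  A spot whose distance quantile equals its minimum distance
degenerates to an indicator of the nearest cell.

**Hotspots.**  The signature score is the standard control-bin score (25
average-expression bins, up to 100 control genes per marker, seeded),
standing in for the module-score routine of the reference tooling with the
same contract: expression-matched background subtraction.  G* uses binary
kNN weights with the focal spot included (the self-inclusive "star"
convention), k = 5 Euclidean neighbors, ties broken by spot index.  The
upper-tail normal p-values are tested at alpha = 0.05 per (spot, type) with
no multiple-testing correction across the S x K tests — this matches the
procedure as designed; users should treat H as a screening mask, not as
calibrated inference.

**Deconvolution.**  Spot profiles are smoothed over the k = 6 nearest
same-cluster spots (self included; small clusters use all members).  The
robust fit is statsmodels RLM with the canonical Huber constant 1.345, at
most 50 IRLS iterations, tolerance 1e-8; non-negativity and the simplex
constraint are imposed by clamp-then-renormalize, which is deterministic
and matches common practice in reference-based deconvolution.  Both the
spot profile y and the basis B live on the **linear** library-normalized
layer (`cp_median`): a spot is a sum of cells only on the linear scale, and
regressing log-transformed sums on log-basis columns misspecifies the
mixture.  On the bundled K = 10 benchmark this choice reduces the
slice-composition RMSE about four-fold relative to the log layer (0.003 vs
0.013).  The hotspot correction V min-max rescales per-cluster hotspot
counts across types (the direction follows from indexing types within a
fixed cluster) and binarizes at tau = 0.01; a cluster with no hotspot
evidence keeps all types, since absence of evidence is not evidence of
absence.  The adjustment `f_t <- (f_t . V_r) / (f_t V_r^T)` never enlarges a
spot's support.

**Cell counts.**  The saturation solve uses G~_ref as the asymptote, as the
estimator's closed form prescribes, with the maximum observed gene count
used only inside the composite reference score; the two conventions differ
and the closed form is followed.  Degenerate logarithm arguments (G~_t >=
G~_ref) saturate to n_max.  `platform.res = High` (or
`max.cells.in.spot = 1`) forces one cell per spot.  In the bundled
intensity sweep the reference spot is computed on the pooled sweep rather
than per dataset: n_max describes the platform's saturation ceiling, which
is a property of the experiment, and per-dataset references at low
intensity would assume the richest ~3-cell spots hold n_max cells,
inflating every estimate several-fold.

**Assignment.**  Per-type sampling targets come from largest-remainder
rounding of `f* x sum(c*)` (conserves the total exactly).  When a type runs
short, each cell is taken once and the remainder re-drawn with replacement;
duplicated cells receive additive zero-mean unit-SD noise on the normalized
layer, clipped at 0, purely to avoid degenerate duplicates.  The
feedforward pre-assignment classifier (hidden layers 64-ReLU/128/128,
dropout 0.2, batch normalization, L2 1e-2, softmax over clusters) is
implemented in numpy with Adam, a 95/5 train/validation split and early
stopping (patience 20, at most 500 epochs); the printed default learning
rate 1e-6 is kept but configurable, since no epoch budget is prescribed and
that rate needs early stopping to terminate sensibly.  Pre-assignment is
skipped for pools of <= 10,000 cells and the matching solved globally.
Rebalancing moves the lowest-margin cells out of the most-over-capacity
cluster first (ties by cluster id), each move reducing total surplus by
one, so it terminates with the demand met exactly.  The matching itself is
`scipy.optimize.linear_sum_assignment` on the slot-expanded similarity;
spots retain their capacity even if no cell of their hotspot types remains
after sampling (flagged rather than dropped).  Jitter is uniform on the
disc via r*sqrt(u) radial sampling.

## Synthetic data

`simulate_sc` draws every gene from a negative binomial with mean 2 and
dispersion (size) 2, multiplies per-cell means by a lognormal library
factor with CV 0.1, and plants `markers_per_type` genes per type at
`fold = 5` times the base mean in their own type.  `simulate_st` lays spots
on a unit grid, draws per-spot cell counts from Poisson(lambda) clamped to
>= 1 (tissue spots are never empty), and fills each spot from its spatial
domain's type profile; domains are Voronoi cells of K uniformly random
seeds, each dominated by one type at weight 0.95 with the remaining 5%
spread over the other types — emulating anatomically dominant regions with
minor infiltration.  Template mode instead samples cells proportionally to
their Pearson correlation (top 2,000 variable genes) with a supplied
template spot, reproducing correlation-driven placement when real spatial
data is available.  A `split_reference` helper produces disjoint
construction/mapping halves.

What the generator does **not** emulate: realistic gene-level sparsity
(every simulated gene is expressed at mean 2, where real transcriptomes are
dominated by near-zero genes), gene-gene correlation beyond type identity,
platform noise (optical contamination, segmentation errors, RNA diffusion
between spots), and irregular tissue geometry.  Consequences worth knowing:
passing tests show the pipeline's machinery is correct under clean
block-structured signal, not that it is robust to real-data artifacts; and
the dense expression regime saturates the detected-gene count within ~4
cells per spot, which degrades the gene-count arm of the saturation
estimator (its RMSE on this generator is several cells per spot even though
the ranking, and hence the correlation with truth, stays high).  On sparse
real data the gene-count arm operates far from saturation, which is the
regime it assumes.

## Evaluation metrics

The accuracy index combines abundance recall a_j with a count-RMSE term.
The printed form `2a(1 - RMSE)^-1` exceeds 1 (and diverges at RMSE = 1),
contradicting its documented [0, 1] range, so the default is the harmonic
mean `2ab/(a + b)` with `b = max(0, 1 - RMSE)` — the only reading that
respects the range and equals 1 for perfect predictions; the literal form
is kept as an option.  SGMA fits a Gaussian to each type's spot scores and
takes the upper tail (p <= 0.01) as the type's score-defined spot set; the
location/scale are estimated robustly (median, lower-quartile scale),
because the fit is meant to describe the null population of non-harboring
spots and moment estimates on the bimodal mixture inflate both parameters —
for types occupying ~20% of the tissue the moment-based tail set is nearly
empty.  The test is one-sided by construction (high scores indicate
presence).  KL divergence uses a Gaussian kernel on a 25 x 25 grid with
bandwidth defaulting to the minimum inter-spot distance (a fixed template
bandwidth would not transfer across datasets), densities floored at 1e-12
and renormalized.  The optional 0-1 rescaling of SGMA across datasets is a
reporting step, available as a post-processor.

## Bundled benchmark sizes

The self-contained benchmarks use a K = 10 reference (3,000 genes, 50
cells/type, 200 markers/type at 5x fold), 1,000-spot datasets per Poisson
intensity in the count sweep (n_max = 25) and a 2,000-spot dataset at
intensity 5 for the composition and SGMA experiments, with 100 resampling
iterations of 2,000 spots.  These sizes keep a full run in the minutes
range on one CPU while leaving every estimate's sampling error well below
the effect sizes being checked.

## Known limitations

- Cell types with similar expression programs compete for the same spots;
  the likelihood cannot separate lineage-close types well.
- The assignment is linear in the similarity; nonlinear cell-spot
  relationships are out of scope.
- Hotspot significance is uncorrected for multiplicity (above).
- The saturation count estimator assumes detected-gene counts are far from
  saturation and that the richest spots actually reach n_max cells; both
  assumptions can fail (see the generator discussion).
- The pre-assignment classifier is a convenience for scale, not a
  calibrated classifier; with few clusters or few spots it can be skipped
  entirely (the default for small pools).
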