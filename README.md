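# spotmap

`spotmap` reconstructs tissue architecture at single-cell resolution by
assigning cells from an annotated single-cell (SC) reference to the capture
spots of a spatial-transcriptomics (ST) dataset.  It is aimed at
low-resolution spatial platforms (e.g. 10x Visium), where each spot mixes
one to ~10 cells, but also runs on near-single-cell platforms by fixing one
cell per spot.

## Method

Given an SC reference **X** (G genes x C cells, K annotated types) and an ST
dataset **Q** (G genes x S spots with coordinates), the pipeline runs:

1. **Marker selection.**  For each gene the per-type mean profile X*_i. is
   scored by a weighted entropy-like specificity
   `spec_i = (w_i / K) * sum_j r_j log2 r_j`, `r_j = X*_ij / mean_j X*_ij`,
   with `w_i` the min-max-scaled row maximum.  `spec_i` is 0 for uniformly
   expressed genes and `w_i log2 K` for type-exclusive ones.  Each gene is
   assigned to its argmax-mean type; unusually variable genes are filtered
   and the top 100 per type form the marker sets Z.
2. **Spot-cell likelihood.**  Each cell's marker expression becomes a
   Laplace-smoothed probability vector p_.j; a spot with marker counts y is
   scored `log10 P(t|j) = sum_i y_i log10 p_ij` (multinomial, constant
   dropped).  Cells and spots are co-embedded (per-dataset scaling, joint
   PCA, UMAP) and each spot's log-likelihood row, min-max scaled to [0, 1],
   is multiplied by a distance weight that falls to zero at a per-spot
   distance quantile (default 0.3) — the spatially weighted similarity P'.
3. **Hotspots.**  Per type, spots are scored with an expression-matched
   signature score and tested with the local Getis-Ord G* statistic over
   k = 5 nearest neighbors (self-inclusive); upper-tail normal p <= 0.05
   defines the boolean hotspot matrix H.  Spots hot for no type are dropped.
4. **Deconvolution.**  Spot marker profiles (smoothed over 6 same-cluster
   neighbors) are regressed on the per-type marker basis B with a Huber
   robust linear model; coefficients are clamped to >= 0 and renormalized so
   `||f_t||_1 = 1`.  A per-cluster binary correction V built from hotspot
   counts zeroes types without spatial evidence, and the corrected rows
   aggregate into the slice composition f*.
5. **Cell counts.**  Per-spot library size L_t and detected-gene count G~_t
   feed a saturation model: a reference spot from the top decile of a
   composite score is assumed to hold `n_max` cells, and
   `c_gsize = log(1 - G~_t/G~_ref) / log(1 - g~/G~_ref)` is combined with
   `c_libsize = L_t / (L_ref/n_max)` by a harmonic mean, rounded and clamped
   to [1, n_max].
6. **Assignment.**  `f* x sum(c*)` candidate cells are sampled per type
   (with replacement plus noise when a type runs short), the similarity is
   penalized by `-(1 - H)` so off-hotspot placements are dominated, each
   spot is expanded into c* slots, and a Jonker-Volgenant-family solver
   finds the maximum-similarity perfect matching (optionally decomposed by
   ST cluster after a small feedforward-network pre-assignment).  Assigned
   cells get uniform jitter inside a disc of half the minimum inter-spot
   distance.

A simulator (negative-binomial SC reference with planted marker blocks;
spots summing Poisson-many cells placed in spatial domains or by template
correlation) and the usual evaluation metrics (accuracy index, HVG
conservation, Jaccard, resampled composition PCC/RMSE, cosine recovery,
kernel-density KL, SGMA, co-existence index) are included.

## Worked example

```sh
spotmap simulate --kind sc --out ref --seed 1 --k-types 3 --genes 300 \
    --cells-per-type 40 --markers-per-type 20
spotmap simulate --kind st --out tissue --seed 2 --sc-counts ref.mtx \
    --sc-labels ref.labels.tsv --n-spots 100 --lam 3
spotmap map --sc-counts ref.mtx --sc-labels ref.labels.tsv \
    --st-counts tissue.mtx --st-coords tissue.coords.csv \
    --out run1 --seed 3 --max-cells-in-spot 8
spotmap metrics --mapping run1/mapping.tsv --truth tissue.truth \
    --out report.json --seed 4
```

which prints

```
wrote SC reference (300 genes x 120 cells) to ref.*
wrote ST dataset (100 spots) + truth to tissue.*
mapped 458 cells onto 86 spots -> run1
{
  "seed": 4,
  "composition_pcc_mean": 0.9912741112188945,
  "composition_rmse_mean": 0.03129545952242956,
  "type_jaccard_mean": 0.83,
  "n_cells_mapped": 458
}
```

458 cells were placed on the 86 spots that passed hotspot filtering; the
mapped slice-level type proportions correlate with the recorded truth at
PCC 0.99 (RMSE 0.03), and on average 83% agreement (Jaccard) holds between
the mapped and true type sets of each spot.  `run1/` holds the per-cell
placements with jittered coordinates, per-spot counts and compositions, the
marker sets and a provenance record.

The same pipeline is available in-process:

```python
import spotmap

sc, planted = spotmap.simulate_sc(K=3, G=300, cells_per_type=40, markers_per_type=20, seed=1)
st, truth = spotmap.simulate_st(sc, n_spots=100, lam=3, seed=2)
out = spotmap.run_map(sc, st, spotmap.RunConfig(seed=3, max_cells_in_spot=8))
print(out.result.n_cells, out.global_composition)
```

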