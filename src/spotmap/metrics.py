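"""Evaluation statistics for cell-to-spot mappings.

Covers the per-type accuracy index (abundance recall combined with a count
RMSE term), HVG conservation, per-spot Jaccard agreement, resampled
slice-composition concordance (PCC/RMSE), cosine expression recovery,
kernel-density KL divergence of spatial distributions, the score-guided
mapping accuracy (SGMA) index, and the pairwise co-existence index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .io import ExpressionMatrix, MappingResult, SCReference, STDataset
from .simulate import SyntheticTruth

__all__ = [
    "accuracy_index",
    "hvg_conservation",
    "spot_jaccard",
    "composition_concordance",
    "expression_recovery",
    "kl_spatial",
    "sgma",
    "coexistence",
    "rescale_unit",
]


def accuracy_index(pred_counts: pd.DataFrame, true_counts: pd.DataFrame,
                   variant: str = "harmonic") -> pd.Series:
    """Per-type mapping accuracy combining abundance recall and count RMSE.

    a_j is the fraction of predicted cells landing in spots where the type
    truly occurs; b_j = max(0, 1 - RMSE) penalizes count errors.  The
    ``harmonic`` variant 2ab/(a+b) stays in [0, 1]; the ``literal`` variant
    2 a (1 - RMSE)^-1 is kept for comparison and may exceed 1.
    """
    pred = pred_counts.reindex(index=true_counts.index,
                               columns=true_counts.columns).fillna(0.0)
    out = {}
    for j in true_counts.columns:
        p = pred[j].to_numpy(dtype=float)
        t = true_counts[j].to_numpy(dtype=float)
        if p.sum() == 0 and t.sum() == 0:
            out[j] = np.nan
            continue
        a = p[t > 0].sum() / p.sum() if p.sum() > 0 else 0.0
        rmse = float(np.sqrt(np.mean((p - t) ** 2)))
        if variant == "harmonic":
            b = max(0.0, 1.0 - rmse)
            out[j] = 0.0 if a + b == 0 else 2 * a * b / (a + b)
        elif variant == "literal":
            out[j] = np.inf if rmse == 1.0 else 2 * a / (1.0 - rmse)
        else:
            raise ValueError(f"unknown variant {variant!r}")
    return pd.Series(out)


def hvg_conservation(set_a, set_b) -> float:
    """|A ∩ B| / min(|A|, |B|) for two highly-variable-gene sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("HVG sets must be nonempty")
    return len(a & b) / min(len(a), len(b))


def spot_jaccard(a: dict[str, set], b: dict[str, set]) -> pd.Series:
    """Per-spot Jaccard index of the two spot -> set maps.

    Spots where both sets are empty score 1 by convention (flagged).
    """
    spots = sorted(set(a) | set(b))
    vals = {}
    flagged = 0
    for s in spots:
        sa, sb = a.get(s, set()), b.get(s, set())
        if not sa and not sb:
            vals[s] = 1.0
            flagged += 1
            continue
        vals[s] = len(sa & sb) / len(sa | sb)
    if flagged:
        warnings.warn(f"{flagged} spot(s) empty on both sides; scored 1 by convention")
    return pd.Series(vals)


def _proportions(counts: pd.DataFrame, spots) -> np.ndarray:
    sub = counts.loc[spots].to_numpy(dtype=float)
    tot = sub.sum()
    return sub.sum(axis=0) / tot if tot > 0 else np.zeros(counts.shape[1])


def composition_concordance(pred_counts: pd.DataFrame, truth: SyntheticTruth,
                            n_spots: int = 2000, n_iter: int = 100,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Resampled slice-level composition agreement.

    Each iteration samples min(n_spots, S) spots without replacement,
    aggregates predicted and true per-spot type counts into slice
    proportions, and records their PCC and RMSE.
    """
    true_counts = truth.type_counts
    pred = pred_counts.reindex(index=true_counts.index,
                               columns=true_counts.columns).fillna(0.0)
    rng = np.random.default_rng(seed)
    spots = np.asarray(true_counts.index)
    take = min(n_spots, spots.size)
    pccs, rmses = [], []
    for _ in range(n_iter):
        chosen = rng.choice(spots, size=take, replace=False)
        p = _proportions(pred, chosen)
        t = _proportions(true_counts, chosen)
        pccs.append(pearsonr(p, t).statistic if p.std() > 0 and t.std() > 0 else 0.0)
        rmses.append(float(np.sqrt(np.mean((p - t) ** 2))))
    return np.asarray(pccs), np.asarray(rmses)


def mapped_type_counts(mapped: MappingResult, spot_ids, type_names) -> pd.DataFrame:
    """Spot x type table of mapped-cell counts."""
    tab = (mapped.records.groupby(["spot_id", "cell_type"]).size().unstack(fill_value=0))
    return tab.reindex(index=spot_ids, columns=type_names).fillna(0).astype(int)


def expression_recovery(mapped: MappingResult, pool_expression: ExpressionMatrix,
                        st: STDataset, n_hvg: int = 2000) -> float:
    """Mean per-spot cosine between recovered and observed profiles.

    The recovered profile sums the expression of the cells assigned to each
    spot; cosines are computed over the ``n_hvg`` most variable ST genes.
    Spots with zero recovered norm are skipped (counted in a warning).
    """
    shared = [g for g in st.matrix.gene_ids if g in set(pool_expression.gene_ids)]
    stx = st.matrix.subset_genes(shared).dense()
    var = stx.var(axis=1)
    top = np.sort(np.argsort(var)[::-1][: min(n_hvg, len(shared))])
    genes = [shared[i] for i in top]
    stx = stx[top]
    poolx = pool_expression.subset_genes(genes).dense()
    col = {c: i for i, c in enumerate(pool_expression.column_ids)}
    spot_pos = {s: i for i, s in enumerate(st.spot_ids)}
    recovered = np.zeros_like(stx)
    for cell_id, spot_id in zip(mapped.records["cell_id"], mapped.records["spot_id"]):
        recovered[:, spot_pos[spot_id]] += poolx[:, col[cell_id]]
    cosines = []
    skipped = 0
    for s in range(stx.shape[1]):
        nr, no = np.linalg.norm(recovered[:, s]), np.linalg.norm(stx[:, s])
        if nr == 0 or no == 0:
            skipped += 1
            continue
        cosines.append(float(recovered[:, s] @ stx[:, s] / (nr * no)))
    if skipped:
        warnings.warn(f"{skipped} spot(s) skipped (zero recovered profile)")
    return float(np.mean(cosines)) if cosines else np.nan


def _grid_density(points: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = ((grid[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    dens = np.exp(-d2 / (2 * bandwidth**2)).sum(axis=1)
    dens = np.maximum(dens, 1e-12)
    return dens / dens.sum()


def kl_spatial(mapped_points: pd.DataFrame, true_points: pd.DataFrame,
               bandwidth: float, grid_n: int = 25) -> pd.Series:
    """Per-type KL(true || mapped) of grid kernel densities.

    Both point sets are frames with cell_type, x, y.  Densities use a
    Gaussian kernel of SD ``bandwidth`` on a grid_n x grid_n grid over the
    joint bounding box, floored at 1e-12 and renormalized.  Types missing on
    one side report infinity.
    """
    all_xy = np.vstack([mapped_points[["x", "y"]], true_points[["x", "y"]]])
    lo, hi = all_xy.min(axis=0), all_xy.max(axis=0)
    gx = np.linspace(lo[0], hi[0], grid_n)
    gy = np.linspace(lo[1], hi[1], grid_n)
    grid = np.array([(x, y) for x in gx for y in gy])
    out = {}
    types = sorted(set(mapped_points["cell_type"]) | set(true_points["cell_type"]))
    for t in types:
        mp = mapped_points.loc[mapped_points["cell_type"] == t, ["x", "y"]].to_numpy()
        tp = true_points.loc[true_points["cell_type"] == t, ["x", "y"]].to_numpy()
        if mp.shape[0] == 0 or tp.shape[0] == 0:
            warnings.warn(f"cell type {t!r} missing on one side; KL = inf")
            out[t] = np.inf
            continue
        pm = _grid_density(mp, grid, bandwidth)
        pt = _grid_density(tp, grid, bandwidth)
        out[t] = float(np.sum(pt * np.log(pt / pm)))
    return pd.Series(out)


def rank_sum_markers(sc: SCReference, normalized: ExpressionMatrix,
                     n_markers: int = 20, logfc_min: float = 0.25,
                     min_pct: float = 0.25) -> dict[str, list[str]]:
    """Wilcoxon rank-sum marker genes per type (one-vs-rest)."""
    import scanpy as scpy
    import anndata as ad

    X = normalized.dense().T
    adata = ad.AnnData(X=X)
    adata.obs_names = normalized.column_ids
    adata.var_names = normalized.gene_ids
    adata.obs["cell_type"] = pd.Categorical(sc.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scpy.tl.rank_genes_groups(adata, "cell_type", method="wilcoxon",
                                  pts=True, n_genes=adata.n_vars)
    result = adata.uns["rank_genes_groups"]
    out: dict[str, list[str]] = {}
    for t in sc.type_index:
        names = np.asarray(result["names"][t])
        lfc = np.asarray(result["logfoldchanges"][t], dtype=float)
        pts = adata.uns["rank_genes_groups"]["pts"][t].loc[names].to_numpy()
        keep = (lfc >= logfc_min) & (pts >= min_pct)
        out[t] = list(names[keep][:n_markers])
    return out


def sgma(mapped_spot_sets: dict[str, set], st: STDataset, sc: SCReference,
         p_cut: float = 0.01, n_markers: int = 20, seed: int = 0,
         sc_normalized: ExpressionMatrix | None = None,
         st_normalized: ExpressionMatrix | None = None,
         ) -> tuple[float, pd.Series]:
    """Score-guided mapping accuracy.

    Rank-sum markers per type are scored on the ST spots; a Gaussian fitted
    to the scores defines high-score spots at upper-tail p <= p_cut, which
    are compared by Jaccard with the spots the mapping assigns the type to.
    The Gaussian location/scale are estimated robustly (median and scaled
    MAD): the fit should describe the null population of non-harboring
    spots, and moment estimates on the bimodal score mixture would inflate
    both parameters and empty the selected set for abundant types.
    Returns (mean index, per-type indices).  Types with no markers are
    excluded from the mean and reported as NaN.
    """
    from .hotspot import signature_score
    from .preprocess import normalize

    scn = sc_normalized if sc_normalized is not None else normalize(sc.matrix)
    stn = st_normalized if st_normalized is not None else normalize(st.matrix)
    marker_map = rank_sum_markers(sc, scn, n_markers=n_markers)
    spot_ids = np.asarray(st.spot_ids)
    per_type = {}
    for i, t in enumerate(sc.type_index):
        genes = [g for g in marker_map.get(t, []) if g in set(stn.gene_ids)]
        if not genes:
            warnings.warn(f"no rank-sum markers for type {t!r}; excluded from SGMA")
            per_type[t] = np.nan
            continue
        scores = signature_score(st, genes, seed=seed + i, normalized=stn)
        # null-component Gaussian fit: median location, lower-quartile scale
        # (contamination by harboring spots is one-sided from above)
        mu = float(np.median(scores))
        sd = (mu - float(np.quantile(scores, 0.25))) / 0.6745
        if sd == 0:
            sd = float(np.std(scores))
        if sd == 0:
            per_type[t] = np.nan
            continue
        pvals = 1.0 - norm.cdf((scores - mu) / sd)
        S_score = set(spot_ids[pvals <= p_cut])
        S_map = set(mapped_spot_sets.get(t, set()))
        union = S_score | S_map
        per_type[t] = len(S_score & S_map) / len(union) if union else np.nan
    series = pd.Series(per_type)
    return float(series.dropna().mean()), series


def coexistence(mapped: MappingResult) -> pd.DataFrame:
    """K x K co-occurrence of types across spots, normalized by the rarer type.

    E_ij = |S_i ∩ S_j| / min(|S_i|, |S_j|); the diagonal is 1 wherever the
    type occurs at all, and types mapped to no spot report NaN.
    """
    sets: dict[str, set] = {}
    for t, g in mapped.records.groupby("cell_type"):
        sets[t] = set(g["spot_id"])
    types = sorted(set(mapped.records["cell_type"]))
    out = pd.DataFrame(np.nan, index=types, columns=types)
    for i in types:
        for j in types:
            si, sj = sets.get(i, set()), sets.get(j, set())
            if not si or not sj:
                continue
            out.loc[i, j] = len(si & sj) / min(len(si), len(sj))
    return out


def rescale_unit(values: pd.Series) -> pd.Series:
    """Optional 0-1 min-max rescaling used when reporting across datasets."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return pd.Series(1.0, index=values.index)
    return (values - lo) / (hi - lo)
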