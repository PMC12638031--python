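"""Cell-type-specific marker selection via an entropy-based specificity score.

For each gene the per-type mean expression profile is turned into ratios
r_j = mean_ij / mean_i (mean over types); the negative Shannon-entropy-like
sum (w_i/K) * sum_j r_j log2 r_j is zero for uniformly expressed genes and
maximal (w_i * log2 K) for genes exclusive to one type.  The weight w_i
min-max scales each gene's best per-type mean so that highly expressed genes
dominate.  Genes are assigned to their argmax-mean type, high-variance
outliers are filtered, and the top n_top per type form the marker sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, SCReference

__all__ = [
    "SpecificityTable",
    "MarkerSet",
    "mean_expression_by_type",
    "gene_weights",
    "specificity_scores",
    "select_markers",
    "compute_specificity_table",
]

VARIANCE_SD_CUTOFF = 3.0  # filter genes > mean + 3 SD of relative variance
VARIANCE_REL_FLOOR = 2.0  # never flag genes below 2x the variance trend
VARIANCE_TREND_WINDOW = 31


def _relative_variance(mean: np.ndarray, var: np.ndarray,
                       window: int = VARIANCE_TREND_WINDOW) -> np.ndarray:
    """Variance divided by the mean-variance trend (running median).

    On any normalization short of a fully variance-stabilizing transform,
    raw variance tracks expression level, so an absolute variance cutoff
    would preferentially discard exactly the highly expressed type-specific
    genes the selection is after.  The trend is the running median of
    variance over genes ordered by mean (centered window), so the filter
    fires only on genes unusually variable *for their expression level*.
    """
    from scipy.ndimage import median_filter

    order = np.argsort(mean, kind="stable")
    window = max(3, min(window, order.size))
    trend_sorted = median_filter(var[order], size=window, mode="nearest")
    trend = np.empty_like(var)
    trend[order] = trend_sorted
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(trend > 0, var / trend, np.where(var > 0, np.inf, 1.0))
    return rel


@dataclass
class SpecificityTable:
    """Per-gene specificity score, weight, assigned type and variance flag."""

    table: pd.DataFrame  # index: gene; columns: spec, weight, assigned_type, variance_pass

    def __post_init__(self) -> None:
        w = self.table["weight"]
        if ((w < -1e-12) | (w > 1 + 1e-12)).any():
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class MarkerSet:
    """Ordered marker-gene lists per cell type (descending specificity)."""

    per_type: dict[str, list[str]]

    @property
    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.per_type.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    @property
    def m(self) -> int:
        return len(self.union)

    def restrict_to(self, genes) -> "MarkerSet":
        """Drop genes outside ``genes`` (e.g. absent from the ST dataset)."""
        keep = set(genes)
        return MarkerSet({t: [g for g in gl if g in keep] for t, gl in self.per_type.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, g, r) for t, gl in self.per_type.items() for r, g in enumerate(gl, 1)]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "rank"])


def mean_expression_by_type(sc: SCReference,
                            normalized: ExpressionMatrix | None = None) -> pd.DataFrame:
    """G x K matrix of per-type mean expression (normalized layer)."""
    mat = normalized if normalized is not None else sc.matrix
    vals = mat.values
    out = np.empty((mat.n_genes, sc.n_types))
    for j, t in enumerate(sc.type_index):
        cols = sc.type_columns(t)
        sub = vals.tocsc()[:, cols] if sp.issparse(vals) else vals[:, cols]
        out[:, j] = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame(out, index=mat.gene_ids, columns=sc.type_index)


def gene_weights(meanX: pd.DataFrame) -> pd.Series:
    """Min-max scaled row maxima of the per-type mean matrix, in [0, 1]."""
    if (meanX.to_numpy() < 0).any():
        raise ValueError("per-type means must be non-negative")
    row_max = meanX.max(axis=1)
    lo = row_max.min()
    hi = meanX.to_numpy().max()
    if hi == lo:
        warnings.warn("constant mean-expression matrix; all gene weights set to 1")
        return pd.Series(1.0, index=meanX.index)
    return (row_max - lo) / (hi - lo)


def specificity_scores(meanX: pd.DataFrame, weights: pd.Series, K: int | None = None) -> pd.Series:
    """spec_i = (w_i / K) * sum_j r_j log2 r_j with r_j = mean_ij / rowmean_i.

    0 * log2(0) is taken as 0; all-zero genes score 0.  Bounded by
    w_i * log2 K (the exclusive-expression case).
    """
    K = K if K is not None else meanX.shape[1]
    x = meanX.to_numpy(dtype=float)
    rowmean = x.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(rowmean > 0, x / rowmean, 0.0)
        term = np.where(r > 0, r * np.log2(r), 0.0)
    spec = (weights.to_numpy() / K) * term.sum(axis=1)
    return pd.Series(np.maximum(spec, 0.0), index=meanX.index)


def compute_specificity_table(sc: SCReference,
                              normalized: ExpressionMatrix | None = None) -> SpecificityTable:
    """Assemble spec scores, weights, argmax types and the variance filter.

    The variance filter works within each assigned type: the per-cell
    expression variance of every gene across that type's cells is computed,
    standardized against the mean-variance trend, and genes assigned to the
    type whose relative variance exceeds the mean (over all genes) by more
    than 3 SD are flagged out.
    """
    mat = normalized if normalized is not None else sc.matrix
    meanX = mean_expression_by_type(sc, mat)
    w = gene_weights(meanX)
    spec = specificity_scores(meanX, w, sc.n_types)
    # argmax type, ties broken by lowest type index (np.argmax is first-max)
    assigned = np.asarray(sc.type_index)[np.argmax(meanX.to_numpy(), axis=1)]
    variance_pass = np.ones(mat.n_genes, dtype=bool)
    vals = mat.values.tocsc() if sp.issparse(mat.values) else mat.values
    for t in sc.type_index:
        cols = sc.type_columns(t)
        sub = vals[:, cols]
        if sp.issparse(sub):
            mean = np.asarray(sub.mean(axis=1)).ravel()
            mean_sq = np.asarray(sub.multiply(sub).mean(axis=1)).ravel()
            var = np.maximum(mean_sq - mean**2, 0.0)
        else:
            mean = sub.mean(axis=1)
            var = sub.var(axis=1)
        rel = _relative_variance(mean, var)
        finite = np.isfinite(rel)
        # floor at 2x the trend: flagging smaller excesses would be within
        # chi-square sampling noise of the per-type variance estimate
        cutoff = max(
            rel[finite].mean() + VARIANCE_SD_CUTOFF * rel[finite].std(),
            VARIANCE_REL_FLOOR,
        )
        mask = assigned == t
        variance_pass[mask & (rel > cutoff)] = False
    table = pd.DataFrame(
        {"spec": spec, "weight": w, "assigned_type": assigned, "variance_pass": variance_pass},
        index=meanX.index,
    )
    return SpecificityTable(table)


def select_markers(sc: SCReference, spec_table: SpecificityTable,
                   n_top: int = 100) -> MarkerSet:
    """Top ``n_top`` variance-filtered genes per type, ranked by specificity.

    Ranking ties are broken by gene order in the input to keep selection
    deterministic; a type left with no qualifying genes is retained with an
    empty list (with a warning).
    """
    tab = spec_table.table
    per_type: dict[str, list[str]] = {}
    for t in sc.type_index:
        sub = tab[(tab["assigned_type"] == t) & tab["variance_pass"]]
        ranked = sub.sort_values("spec", ascending=False, kind="stable")
        genes = list(ranked.index[:n_top])
        if not genes:
            warnings.warn(f"no qualifying marker genes for cell type {t!r}")
        per_type[t] = genes
    return MarkerSet(per_type)
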