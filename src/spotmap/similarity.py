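"""Spatially weighted likelihood linking spots to single cells.

Each cell's marker-gene expression is turned into a Laplace-smoothed
probability vector; a spot's marker counts are scored against every cell
under a multinomial model (log10 likelihood, constant term dropped).  The
joint-embedding distance between a spot and each cell is converted into a
[0, 1] weight that vanishes beyond a per-spot distance quantile, and the
min-max-scaled log-likelihood row is multiplied by that weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, SCReference, STDataset
from .markers import MarkerSet
from .preprocess import JointEmbedding

__all__ = [
    "ProbabilityMatrix",
    "SimilarityMatrix",
    "DistanceWeightMatrix",
    "cell_gene_probabilities",
    "log_likelihood",
    "distance_weights",
    "weighted_similarity",
]

LAPLACE = 1e-6


@dataclass
class ProbabilityMatrix:
    """m x C per-cell probability vectors over the marker-gene union."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            raise ValueError("smoothed probabilities must be strictly positive")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("probability columns must sum to 1")


@dataclass
class SimilarityMatrix:
    """S x C spot-by-cell similarity (log-likelihoods or weighted scores)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity values must be finite")


@dataclass
class DistanceWeightMatrix:
    """S x C distance-derived weights in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("distance weights must lie in [0, 1]")


def cell_gene_probabilities(sc: SCReference, markers: MarkerSet,
                            normalized: ExpressionMatrix | None = None,
                            laplace: float = LAPLACE) -> ProbabilityMatrix:
    """p_ij = (laplace + x_ij) / sum_i (laplace + x_ij) over marker genes."""
    genes = markers.union
    if not genes:
        raise ValueError("marker union is empty")
    mat = normalized if normalized is not None else sc.matrix
    x = mat.subset_genes(genes).dense()
    x = x + laplace
    p = x / x.sum(axis=0, keepdims=True)
    return ProbabilityMatrix(p, genes, list(mat.column_ids))


def log_likelihood(st: STDataset, probs: ProbabilityMatrix) -> SimilarityMatrix:
    """Multinomial log10-likelihood of each spot's marker counts per cell.

    Entry (t, j) = sum_i y_ti * log10 p_ij; the multinomial coefficient is a
    per-spot constant and dropped.  Spots with zero marker counts get a row
    of zeros (flagged with a warning).
    """
    y = st.matrix.subset_genes(probs.gene_ids).values
    y = np.asarray(y.todense(), dtype=float) if sp.issparse(y) else np.asarray(y, dtype=float)
    zero_rows = np.flatnonzero(y.sum(axis=0) == 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} spot(s) have zero marker counts; their "
            "likelihood rows are all zero"
        )
    ll = y.T @ np.log10(probs.values)
    return SimilarityMatrix(ll, list(st.spot_ids), list(probs.cell_ids))


def distance_weights(embed: JointEmbedding, probs_quantile: float = 0.3) -> DistanceWeightMatrix:
    """Per-spot scaled distance weights in the 2D embedding.

    D'_tj = (q_t - d_tj) / (q_t - min_j d_tj) with q_t the ``probs_quantile``
    quantile of spot t's distance vector; negatives clamp to 0.  A degenerate
    row (q_t equals the minimum) becomes the indicator of the nearest cell.
    """
    if not (0.01 <= probs_quantile <= 1.0):
        raise ValueError("probs_quantile must lie in [0.01, 1]")
    from scipy.spatial.distance import cdist

    d = cdist(embed.spot_coords, embed.cell_coords)
    q = np.quantile(d, probs_quantile, axis=1, keepdims=True)
    dmin = d.min(axis=1, keepdims=True)
    out = np.zeros_like(d)
    degenerate = (q - dmin).ravel() <= 0
    ok = ~degenerate
    if ok.any():
        out[ok] = np.clip((q[ok] - d[ok]) / (q[ok] - dmin[ok]), 0.0, 1.0)
    for t in np.flatnonzero(degenerate):
        out[t, int(np.argmin(d[t]))] = 1.0
    return DistanceWeightMatrix(out)


def weighted_similarity(loglik: SimilarityMatrix,
                        dweights: DistanceWeightMatrix) -> SimilarityMatrix:
    """Min-max scale each spot's log-likelihood row to [0, 1], then apply D'."""
    if loglik.values.shape != dweights.values.shape:
        raise ValueError("log-likelihood and distance-weight shapes differ")
    ll = loglik.values
    lo = ll.min(axis=1, keepdims=True)
    hi = ll.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} spot row(s) have constant likelihood; set to 0")
    span[span == 0] = 1.0
    scaled = (ll - lo) / span
    scaled[flat] = 0.0
    return SimilarityMatrix(scaled * dweights.values, list(loglik.row_ids), list(loglik.col_ids))
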