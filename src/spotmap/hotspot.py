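"""Per-type spatial hotspot detection with the Getis-Ord G* statistic.

Each cell type's marker set is scored on every spot with an
expression-matched control score (mean over the set minus the mean over
control genes drawn from the same average-expression bins).  The local G*
statistic then asks whether a spot's k-nearest-neighborhood (self included)
deviates from the slice-wide mean score; upper-tail normal p-values at level
alpha define the boolean spot-by-type hotspot matrix H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, STDataset
from .markers import MarkerSet

__all__ = [
    "HotspotMatrix",
    "signature_score",
    "getis_ord_gstar",
    "hotspot_matrix",
]


@dataclass
class HotspotMatrix:
    """S x K boolean hotspot map plus the retained-spot subset S'."""

    values: pd.DataFrame  # index: spot ids, columns: type names, bool
    retained_spots: list[str]

    def __post_init__(self) -> None:
        if not self.retained_spots:
            raise ValueError("no spot is a hotspot for any cell type")

    @property
    def spot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def type_names(self) -> list[str]:
        return list(self.values.columns)


def signature_score(st: STDataset, gene_set: list[str], n_bins: int = 25,
                    n_ctrl: int = 100, seed: int = 0,
                    normalized: ExpressionMatrix | None = None) -> np.ndarray:
    """Expression-matched signature score per spot.

    Genes are binned by slice-average expression (``n_bins`` bins); for each
    gene in the set, ``n_ctrl`` control genes are sampled from its bin.  The
    score is mean(set) - mean(controls), evaluated on the normalized layer.
    """
    from .preprocess import normalize

    mat = normalized if normalized is not None else normalize(st.matrix)
    genes = [g for g in gene_set if g in set(mat.gene_ids)]
    if not genes:
        raise ValueError("gene set has no overlap with the ST genes")
    x = mat.dense()  # genes x spots
    gene_mean = x.mean(axis=1)
    order = np.argsort(gene_mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    n_bins = min(n_bins, len(gene_mean))
    bins = (ranks * n_bins) // len(gene_mean)
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(mat.gene_ids)}
    set_idx = np.array([idx[g] for g in genes])
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, pool.size)
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.unique(np.concatenate(ctrl_idx))
    return x[set_idx].mean(axis=0) - x[ctrl].mean(axis=0)


def getis_ord_gstar(scores: np.ndarray, coords: np.ndarray,
                    k_neighbors: int = 5) -> np.ndarray:
    """Local G* z-scores over a kNN neighborhood (self-inclusive).

    G*_t = sum_t' theta_tt' (x_t' - xbar) /
           (Delta * sqrt[(S * sum theta^2 - (sum theta)^2) / (S - 1)])
    with binary theta marking t's k nearest neighbors plus t itself.
    """
    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords, dtype=float)
    S = scores.size
    if k_neighbors >= S:
        raise ValueError("k_neighbors must be smaller than the number of spots")
    delta = scores.std()
    if delta == 0:
        warnings.warn("constant signature scores; G* is 0 everywhere")
        return np.zeros(S)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, nbr = nn.kneighbors(coords)  # includes self at distance 0
    xbar = scores.mean()
    dev = scores - xbar
    num = dev[nbr].sum(axis=1)
    w = k_neighbors + 1  # sum of binary weights incl. self
    denom = delta * np.sqrt((S * w - w**2) / (S - 1))
    return num / denom


def hotspot_matrix(st: STDataset, markers: MarkerSet, alpha: float = 0.05,
                   k_neighbors: int = 5, seed: int = 0,
                   normalized: ExpressionMatrix | None = None,
                   n_bins: int = 25, n_ctrl: int = 100) -> HotspotMatrix:
    """Boolean S x K hotspot matrix from per-type G* upper-tail tests.

    p_tj = 1 - Phi(G*_tj); spot t is a hotspot for type j iff p_tj <= alpha.
    Spots significant for no type are dropped from the retained subset.
    """
    if not markers.per_type:
        raise ValueError("empty marker set")
    from .preprocess import normalize

    mat = normalized if normalized is not None else normalize(st.matrix)
    cols: dict[str, np.ndarray] = {}
    for i, (t, genes) in enumerate(markers.per_type.items()):
        if not genes:
            cols[t] = np.zeros(st.n_spots, dtype=bool)
            continue
        scores = signature_score(st, genes, n_bins=n_bins, n_ctrl=n_ctrl,
                                 seed=seed + i, normalized=mat)
        gstar = getis_ord_gstar(scores, st.coords, k_neighbors=k_neighbors)
        pvals = 1.0 - norm.cdf(gstar)
        cols[t] = pvals <= alpha
    H = pd.DataFrame(cols, index=st.spot_ids)
    retained = list(H.index[H.any(axis=1)])
    if not retained:
        raise ValueError(
            "no spot is significant for any cell type; consider a larger alpha"
        )
    return HotspotMatrix(H, retained)
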