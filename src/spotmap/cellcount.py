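"""Per-spot cell-count estimation via a corrected saturation model.

The number of distinct genes detected in a spot saturates as more cells pile
in, while library size keeps growing roughly linearly.  A reference spot —
the mean of the spots with the highest composite library-size/gene-count
score — is assumed to hold ``n_max`` cells; inverting the saturation curve
gives a gene-count-based estimate, the library-size ratio gives a second
estimate, and their harmonic mean (rounded, clamped to [1, n_max]) is the
reported count.  High-resolution platforms force one cell per spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import STDataset

__all__ = [
    "CellCounts",
    "spot_summaries",
    "reference_spot",
    "estimate_counts",
]


@dataclass
class CellCounts:
    """Integer per-spot counts plus the model intermediates."""

    counts: pd.Series            # int, 1..n_max
    c_gsize: np.ndarray
    c_libsize: np.ndarray
    reference: dict              # L_ref, G_ref, g_tilde, l
    n_max: int

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if c.size and (c.min() < 1 or c.max() > self.n_max):
            raise ValueError("counts must lie in [1, n_max]")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def spot_summaries(st: STDataset, min_umi: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Library size L_t and detected-gene count per spot.

    L_t sums all UMIs; the gene count tallies genes whose UMI count reaches
    ``min_umi`` (the low-expression noise floor).
    """
    vals = st.matrix.values
    if st.matrix.layer_tag != "counts":
        raise ValueError("spot summaries require the counts layer")
    if sp.issparse(vals):
        L = np.asarray(vals.sum(axis=0)).ravel()
        G = np.asarray((vals >= min_umi).sum(axis=0)).ravel().astype(float)
    else:
        L = vals.sum(axis=0)
        G = (vals >= min_umi).sum(axis=0).astype(float)
    return L.astype(float), G


def reference_spot(L: np.ndarray, G: np.ndarray, w_L: float = 0.5,
                   w_G: float = 0.5, q: float = 0.90) -> tuple[float, float]:
    """Mean L and gene count over the top-composite-score spots.

    The composite score is w_L * L/L_max + w_G * G/G_max; spots above its
    q-quantile form the reference pool (assumed to hold n_max cells each).
    Falls back to the single best spot if the pool is empty.
    """
    if not np.isclose(w_L + w_G, 1.0):
        raise ValueError("weights must sum to 1")
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    Lmax = L.max() if L.max() > 0 else 1.0
    Gmax = G.max() if G.max() > 0 else 1.0
    score = w_L * L / Lmax + w_G * G / Gmax
    cut = np.quantile(score, q)
    pool = np.flatnonzero(score > cut)
    if pool.size == 0:
        pool = np.array([int(np.argmax(score))])
    return float(L[pool].mean()), float(G[pool].mean())


def estimate_counts(L: np.ndarray, G: np.ndarray, L_ref: float, G_ref: float,
                    n_max: int = 10, spot_ids: list[str] | None = None,
                    high_resolution: bool = False) -> CellCounts:
    """Invert the saturation model and combine with the library-size ratio.

    c_gsize solves G_t = G_ref * (1 - (1 - g/G_ref)^c) with g = G_ref/n_max;
    c_libsize = L_t / (L_ref/n_max).  The harmonic mean of the two (each
    floored at 1) is rounded and clamped to [1, n_max].  Degenerate logs
    (G_t >= G_ref) saturate to n_max.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    ids = spot_ids if spot_ids is not None else [str(i) for i in range(L.size)]
    if high_resolution or n_max == 1:
        ones = pd.Series(np.ones(L.size, dtype=int), index=ids)
        ref = {"L_ref": L_ref, "G_ref": G_ref, "g_tilde": G_ref, "l": L_ref}
        return CellCounts(ones, np.ones(L.size), np.ones(L.size), ref, max(n_max, 1))
    if G_ref <= 0:
        raise ValueError("reference gene count must be positive")
    g = G_ref / n_max
    l = L_ref / n_max
    base = np.log1p(-g / G_ref)  # log(1 - 1/n_max) < 0
    ratio = G / G_ref
    c_gsize = np.full(L.size, float(n_max))
    interior = ratio < 1.0
    with np.errstate(divide="ignore"):
        c_gsize[interior] = np.log1p(-ratio[interior]) / base
    c_gsize[G <= 0] = 1.0
    c_libsize = L / l if l > 0 else np.ones(L.size)
    harm = 2.0 / (1.0 / np.maximum(c_gsize, 1.0) + 1.0 / np.maximum(c_libsize, 1.0))
    counts = np.clip(np.rint(harm), 1, n_max).astype(int)
    ref = {"L_ref": float(L_ref), "G_ref": float(G_ref), "g_tilde": float(g), "l": float(l)}
    return CellCounts(pd.Series(counts, index=ids), c_gsize, c_libsize, ref, n_max)
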