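"""Reference-based spot deconvolution with hotspot correction.

Each retained spot's marker-gene profile (smoothed over same-cluster
neighbors) is regressed on the base matrix of per-type marker means with a
Huber robust linear model; negative coefficients are clamped and the vector
renormalized onto the simplex.  A per-cluster correction matrix built from
hotspot memberships then zeroes out types without spatial evidence before
spot compositions are aggregated into the slice-level proportion vector f*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .hotspot import HotspotMatrix
from .io import ExpressionMatrix, SCReference, STDataset
from .markers import MarkerSet, mean_expression_by_type
from .preprocess import SpotClusters

__all__ = [
    "BaseMatrix",
    "CompositionMatrix",
    "CorrectionMatrix",
    "build_base_matrix",
    "smooth_spot_profile",
    "rlm_deconvolve",
    "deconvolve_spots",
    "correction_matrix",
    "adjust_and_aggregate",
]

HUBER_T = 1.345
RLM_MAXITER = 50
RLM_TOL = 1e-8


@dataclass
class BaseMatrix:
    """m x K matrix of per-type mean marker expression."""

    values: pd.DataFrame  # index: marker genes (union order), columns: types

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("base matrix must be non-negative")


@dataclass
class CompositionMatrix:
    """S' x K spot compositions; rows on the probability simplex."""

    values: pd.DataFrame
    zeroed_spots: list[str]

    def __post_init__(self) -> None:
        rows = self.values.to_numpy()
        sums = rows.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            raise ValueError("composition rows must sum to 1 (or be flagged zero)")


@dataclass
class CorrectionMatrix:
    """R x K binary per-cluster type admissibility."""

    values: pd.DataFrame  # index: cluster id 1..R

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("correction matrix must be binary")


def build_base_matrix(sc: SCReference, markers: MarkerSet,
                      normalized: ExpressionMatrix | None = None) -> BaseMatrix:
    """Mean expression of each marker gene per type, rows in union order."""
    genes = [g for g in markers.union if g in set(sc.matrix.gene_ids)]
    if not genes:
        raise ValueError("no marker gene present in the SC reference")
    meanX = mean_expression_by_type(sc, normalized)
    return BaseMatrix(meanX.loc[genes])


def smooth_spot_profile(st: STDataset, clusters: SpotClusters, genes: list[str],
                        k_smooth: int = 6,
                        normalized: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Average each spot's marker vector over its k nearest same-cluster spots.

    The spot itself is included; clusters smaller than ``k_smooth`` average
    over all their members.  Returns a spots x genes frame.
    """
    from sklearn.neighbors import NearestNeighbors

    from .preprocess import normalize

    mat = normalized if normalized is not None else normalize(st.matrix)
    x = mat.subset_genes(genes).dense().T  # spots x genes
    out = np.empty_like(x)
    for r in range(1, clusters.R + 1):
        members = clusters.members(r)
        if members.size == 0:
            continue
        k = int(min(k_smooth, members.size))
        if k <= 1:
            out[members] = x[members]
            continue
        nn = NearestNeighbors(n_neighbors=k).fit(st.coords[members])
        _, nbr = nn.kneighbors(st.coords[members])
        out[members] = x[members[nbr]].mean(axis=1)
    return pd.DataFrame(out, index=st.spot_ids, columns=genes)


def rlm_deconvolve(y: np.ndarray, B: BaseMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Estimate a simplex composition vector for one spot.

    Huber IRLS regression of the (smoothed) marker profile on the base
    matrix; negative coefficients clamp to 0 and the rest renormalize to
    sum 1.  Returns the zero vector if every coefficient vanishes.
    """
    Bv = B.values.to_numpy() if isinstance(B, BaseMatrix) else np.asarray(
        B.to_numpy() if isinstance(B, pd.DataFrame) else B, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != Bv.shape[0]:
        raise ValueError("profile and base matrix gene orders differ")
    if np.linalg.matrix_rank(Bv) < Bv.shape[1]:
        warnings.warn("rank-deficient base matrix; adding ridge jitter")
        Bv = Bv + 1e-8 * np.random.default_rng(0).standard_normal(Bv.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(y, Bv, M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
            maxiter=RLM_MAXITER, tol=RLM_TOL)
    coef = np.clip(fit.params, 0.0, None)
    total = coef.sum()
    if total == 0:
        return np.zeros_like(coef)
    return coef / total


def deconvolve_spots(profiles: pd.DataFrame, B: BaseMatrix,
                     spot_ids: list[str] | None = None) -> CompositionMatrix:
    """Run the robust regression for every requested spot."""
    ids = list(profiles.index) if spot_ids is None else list(spot_ids)
    genes = list(B.values.index)
    rows = np.vstack([rlm_deconvolve(profiles.loc[s, genes].to_numpy(), B) for s in ids])
    zeroed = [s for s, r in zip(ids, rows) if r.sum() == 0]
    if zeroed:
        warnings.warn(f"{len(zeroed)} spot(s) deconvolved to the zero vector")
    return CompositionMatrix(pd.DataFrame(rows, index=ids, columns=B.values.columns), zeroed)


def correction_matrix(H: HotspotMatrix, clusters: SpotClusters,
                      tau: float = 0.01) -> CorrectionMatrix:
    """Per-cluster hotspot-count profile, min-max rescaled and binarized.

    For cluster r, count per type how many of its spots are hotspots, rescale
    the K counts to [0, 1] and keep types at or above ``tau``.  A cluster with
    no hotspot membership at all keeps every type (no evidence to exclude).
    """
    Hv = H.values
    spot_order = list(Hv.index)
    rows = []
    for r in range(1, clusters.R + 1):
        members = clusters.members(r)
        spots = [spot_order[i] for i in members]
        counts = Hv.loc[spots].sum(axis=0).to_numpy(dtype=float) if spots else np.zeros(Hv.shape[1])
        if counts.max() == 0:
            warnings.warn(f"cluster {r} has no hotspot evidence; keeping all types")
            rows.append(np.ones_like(counts))
            continue
        lo, hi = counts.min(), counts.max()
        scaled = (counts - lo) / (hi - lo) if hi > lo else np.ones_like(counts)
        rows.append((scaled >= tau).astype(float))
    return CorrectionMatrix(pd.DataFrame(
        np.vstack(rows), index=range(1, clusters.R + 1), columns=Hv.columns))


def adjust_and_aggregate(F: CompositionMatrix, V: CorrectionMatrix,
                         clusters: SpotClusters, H: HotspotMatrix,
                         ) -> tuple[CompositionMatrix, pd.Series]:
    """Apply the cluster correction to each spot and aggregate to f*.

    f_t <- (f_t * V_r) / (f_t . V_r) for spot t in cluster r; a spot whose
    admissible types all have zero weight keeps its row (flagged).  The
    slice-level composition f* is the column sum of adjusted rows,
    normalized to 1.
    """
    Fv = F.values.copy()
    spot_pos = {s: i for i, s in enumerate(H.spot_ids)}
    unadjusted: list[str] = []
    for s in Fv.index:
        r = int(clusters.labels[spot_pos[s]])
        v = V.values.loc[r].to_numpy()
        f = Fv.loc[s].to_numpy()
        denom = float(f @ v)
        if denom == 0:
            unadjusted.append(s)
            continue
        Fv.loc[s] = f * v / denom
    if unadjusted:
        warnings.warn(f"{len(unadjusted)} spot(s) left unadjusted (no admissible mass)")
    col = Fv.sum(axis=0)
    total = col.sum()
    if total == 0:
        raise ValueError("all spot compositions are zero; cannot aggregate")
    fstar = col / total
    return CompositionMatrix(Fv, F.zeroed_spots), fstar
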