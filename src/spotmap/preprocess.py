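"""Normalization, spot clustering and the joint SC-ST embedding.

Normalization offers two variance-stabilizing transforms: ``log_cp_median``
(log counts-per-median-library) and ``pearson_residual`` (negative-binomial
Pearson residuals at a fixed dispersion, clipped at +/- sqrt(n_columns)).
Spot clustering follows the standard single-cell workflow — top HVGs, 30 PCs,
kNN graph, leiden community detection.  The joint embedding z-scales shared
genes per dataset, concatenates cells and spots, reduces to ``n_pcs``
principal components and projects to 2D with UMAP; the PC coordinates are
kept for the cluster pre-assignment classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, SCReference, STDataset

__all__ = [
    "SpotClusters",
    "JointEmbedding",
    "normalize",
    "cluster_spots",
    "joint_embed",
]

PEARSON_DISPERSION = 100.0  # NB dispersion for the pearson_residual transform
KNN_GRAPH_K = 20


@dataclass
class SpotClusters:
    """Per-spot cluster labels in 1..R."""

    labels: np.ndarray  # int, one per spot
    R: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.R < 1 or self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.R:
            raise ValueError("cluster labels must lie in 1..R")

    def members(self, r: int) -> np.ndarray:
        return np.flatnonzero(self.labels == r)


@dataclass
class JointEmbedding:
    """Shared 2D projection (and PC space) of cells and spots."""

    cell_coords: np.ndarray  # (C, 2)
    spot_coords: np.ndarray  # (S, 2)
    cell_pcs: np.ndarray     # (C, n_pcs)
    spot_pcs: np.ndarray     # (S, n_pcs)

    def __post_init__(self) -> None:
        for arr in (self.cell_coords, self.spot_coords, self.cell_pcs, self.spot_pcs):
            if not np.all(np.isfinite(arr)):
                raise ValueError("embedding coordinates must be finite")
        if self.cell_coords.shape[1] != self.spot_coords.shape[1]:
            raise ValueError("cells and spots must share embedding dimensionality")


def _library_sizes(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.sum(axis=0)).ravel()
    return values.sum(axis=0)


def normalize(matrix: ExpressionMatrix, method: str = "log_cp_median") -> ExpressionMatrix:
    """Return a normalized copy of a counts matrix.

    ``log_cp_median``: x -> ln(1 + x * m / L) with L the column library size
    and m the median library size.  ``cp_median`` is the same library scaling
    without the log — the layer on which mixtures of cells stay linear.
    ``pearson_residual``: NB Pearson residual (x - mu)/sqrt(mu + mu^2/theta)
    with mu the outer-product expectation and theta fixed, clipped to
    +/- sqrt(n_columns).
    """
    if matrix.layer_tag != "counts":
        raise ValueError("normalize expects a counts layer")
    lib = _library_sizes(matrix.values)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"zero-library column(s): {[matrix.column_ids[i] for i in zero[:5]]}"
        )
    if method in ("log_cp_median", "cp_median"):
        m = float(np.median(lib))
        vals = matrix.values.tocsc().astype(float) if sp.issparse(matrix.values) else matrix.values.astype(float)
        scale = m / lib
        if sp.issparse(vals):
            vals = vals @ sp.diags(scale)
            if method == "log_cp_median":
                vals.data = np.log1p(vals.data)
        else:
            vals = vals * scale[None, :]
            if method == "log_cp_median":
                vals = np.log1p(vals)
        return ExpressionMatrix(vals, list(matrix.gene_ids), list(matrix.column_ids), "normalized")
    if method == "pearson_residual":
        x = matrix.dense()
        total = x.sum()
        mu = np.outer(x.sum(axis=1), lib) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            res = (x - mu) / np.sqrt(mu + mu**2 / PEARSON_DISPERSION)
        res[~np.isfinite(res)] = 0.0
        clip = np.sqrt(matrix.n_columns)
        return ExpressionMatrix(
            np.clip(res, -clip, clip), list(matrix.gene_ids), list(matrix.column_ids), "normalized"
        )
    raise ValueError(f"unknown normalization method {method!r}")


def _to_anndata(matrix: ExpressionMatrix):
    import anndata as ad

    X = matrix.values.T.tocsr() if sp.issparse(matrix.values) else matrix.values.T.copy()
    adata = ad.AnnData(X=np.asarray(X.todense()) if sp.issparse(X) else X)
    adata.obs_names = matrix.column_ids
    adata.var_names = matrix.gene_ids
    return adata


def cluster_spots(st: STDataset, n_hvg: int = 3000, resolution: float = 0.2,
                  seed: int = 0, normalized: ExpressionMatrix | None = None) -> SpotClusters:
    """Graph-based community labels for ST spots.

    Uses the ``n_hvg`` most variable genes, 30 PCs, a kNN graph (k = 20) and
    leiden modularity optimization at the given resolution.  Labels are
    renumbered 1..R in order of first appearance so the output is independent
    of leiden's internal label order; deterministic under a fixed seed.
    """
    import scanpy as sc

    mat = normalized if normalized is not None else normalize(st.matrix)
    if mat.layer_tag != "normalized":
        raise ValueError("cluster_spots expects a normalized layer")
    n_spots = st.n_spots
    if n_spots <= KNN_GRAPH_K:
        warnings.warn("fewer spots than kNN k; falling back to a single cluster")
        return SpotClusters(np.ones(n_spots, dtype=int), 1)
    adata = _to_anndata(mat)
    var = np.asarray(adata.X).var(axis=0)
    if np.allclose(var, 0):
        return SpotClusters(np.ones(n_spots, dtype=int), 1)
    n_hvg = min(n_hvg, adata.n_vars)
    order = np.argsort(var)[::-1][:n_hvg]
    adata = adata[:, np.sort(order)].copy()
    n_pcs = int(min(30, adata.n_obs - 1, adata.n_vars - 1))
    sc.pp.scale(adata, max_value=10)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=KNN_GRAPH_K, use_rep="X_pca", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg", key_added="cluster")
    raw = adata.obs["cluster"].astype(int).to_numpy()
    # stable 1..R renumbering by first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n_spots, dtype=int)
    for i, c in enumerate(raw):
        labels[i] = remap.setdefault(c, len(remap) + 1)
    return SpotClusters(labels, len(remap))


def _zscale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def joint_embed(sc_ref: SCReference, st: STDataset, genes: list[str],
                n_pcs: int = 30, seed: int = 0,
                sc_normalized: ExpressionMatrix | None = None,
                st_normalized: ExpressionMatrix | None = None) -> JointEmbedding:
    """Co-embed SC cells and ST spots into a shared 2D space.

    Shared genes are z-scaled per dataset (a light-weight integration that
    removes dataset-specific location/scale per gene), the column blocks are
    concatenated, reduced with PCA and projected with UMAP.
    """
    from sklearn.decomposition import PCA

    genes = [g for g in genes
             if g in set(sc_ref.matrix.gene_ids) and g in set(st.matrix.gene_ids)]
    if len(genes) < 3:
        raise ValueError("need at least 3 genes shared by SC and ST for embedding")
    sc_mat = sc_normalized if sc_normalized is not None else normalize(sc_ref.matrix)
    st_mat = st_normalized if st_normalized is not None else normalize(st.matrix)
    a = _zscale(sc_mat.subset_genes(genes).dense())
    b = _zscale(st_mat.subset_genes(genes).dense())
    joint = np.hstack([a, b]).T  # entities x genes
    n_pcs = int(min(n_pcs, joint.shape[0] - 1, joint.shape[1]))
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(joint)
    coords = _umap_2d(pcs, seed)
    C = sc_mat.n_columns
    return JointEmbedding(coords[:C], coords[C:], pcs[:C], pcs[C:])


def _umap_2d(pcs: np.ndarray, seed: int) -> np.ndarray:
    import umap

    n_neighbors = int(min(15, max(2, pcs.shape[0] - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed, min_dist=0.3)
        return reducer.fit_transform(pcs).astype(float)
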