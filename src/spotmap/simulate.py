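"""Synthetic single-cell references and spatial datasets with ground truth.

The SC generator plants marker-gene blocks on a negative-binomial background
(per-gene mean 2, dispersion 2 by default) with a lognormal per-cell library
factor; markers are ``fold`` times overexpressed in their own type.  The ST
generator lays spots on a grid, draws each spot's cell count from a clamped
Poisson and fills it with cells drawn either from spatial-domain mixture
profiles (Voronoi domains dominated by one type) or, in template mode, with
probability proportional to each cell's correlation with a real template
spot.  Spot expression is the exact sum of the chosen cells' counts, and
everything needed for evaluation — constituent cells, per-type counts,
domain labels, coordinates — is recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, SCReference, STDataset
from .markers import MarkerSet

__all__ = [
    "SyntheticTruth",
    "simulate_sc",
    "perturb_genes",
    "simulate_st",
    "split_reference",
]

NB_MEAN = 2.0
NB_DISPERSION = 2.0  # NB size parameter r; var = mu + mu^2 / r
LIBRARY_CV = 0.1
DOMAIN_PURITY = 0.95  # weight of the dominant type in a domain's profile


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated spatial dataset."""

    cell_records: pd.DataFrame   # placed_id, source_id, cell_type, spot_id, x, y
    type_counts: pd.DataFrame    # spots x types, integer
    domain_labels: pd.Series     # per spot
    lam: float

    def __post_init__(self) -> None:
        if (self.type_counts.sum(axis=1) < 1).any():
            raise ValueError("every spot must contain at least one cell")
        self.type_counts = self.type_counts.rename_axis("spot_id")

    @property
    def totals(self) -> pd.Series:
        return self.type_counts.sum(axis=1)

    def cells_of_spot(self, spot_id: str) -> list[str]:
        rec = self.cell_records
        return list(rec.loc[rec["spot_id"] == spot_id, "source_id"])

    def type_spot_sets(self) -> dict[str, set]:
        """Spots truly containing at least one cell of each type."""
        return {
            t: set(self.type_counts.index[self.type_counts[t] > 0])
            for t in self.type_counts.columns
        }

    def global_proportions(self) -> pd.Series:
        tot = self.type_counts.sum(axis=0)
        return tot / tot.sum()

    # -- serialization -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.cell_records.to_csv(prefix.with_suffix(".cells.tsv"), sep="\t", index=False)
        self.type_counts.rename_axis("spot_id").to_csv(
            prefix.with_suffix(".type_counts.tsv"), sep="\t")
        meta = {"lam": self.lam,
                "domains": {s: int(d) for s, d in self.domain_labels.items()}}
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix: str | Path) -> "SyntheticTruth":
        prefix = Path(prefix)
        cells = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t",
                            dtype={"placed_id": str, "source_id": str,
                                   "cell_type": str, "spot_id": str})
        counts = pd.read_csv(prefix.with_suffix(".type_counts.tsv"), sep="\t",
                             index_col="spot_id")
        counts.index = counts.index.astype(str)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        domains = pd.Series(meta["domains"])
        return cls(cells, counts, domains, float(meta["lam"]))


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_sc(K: int, G: int, cells_per_type: int, markers_per_type: int,
                fold: float = 5.0, seed: int = 0, nb_mean: float = NB_MEAN,
                nb_dispersion: float = NB_DISPERSION,
                library_cv: float = LIBRARY_CV) -> tuple[SCReference, MarkerSet]:
    """Simulate an annotated SC reference with planted marker blocks.

    Gene block j (``markers_per_type`` genes) has mean ``fold * nb_mean`` in
    type j and ``nb_mean`` elsewhere; remaining genes are flat background.
    Counts are negative binomial with size ``nb_dispersion``; per-cell means
    are scaled by a lognormal library factor (CV ``library_cv``).
    """
    if K * markers_per_type > G:
        raise ValueError("marker blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(G)]
    types = [f"type{j:02d}" for j in range(K)]
    mean_by_type = np.full((G, K), nb_mean)
    planted: dict[str, list[str]] = {}
    for j in range(K):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        mean_by_type[block, j] = nb_mean * fold
        planted[types[j]] = genes[block]
    cols = []
    labels: list[str] = []
    cell_ids: list[str] = []
    r = nb_dispersion
    for j, t in enumerate(types):
        lib = _library_factors(rng, cells_per_type, library_cv)
        mu = mean_by_type[:, [j]] * lib[None, :]
        counts = rng.negative_binomial(r, r / (r + mu))
        cols.append(counts)
        labels.extend([t] * cells_per_type)
        cell_ids.extend(f"{t}_c{i:04d}" for i in range(cells_per_type))
    matrix = ExpressionMatrix(np.hstack(cols).astype(np.int64), genes, cell_ids, "counts")
    return SCReference(matrix, labels, types), MarkerSet(planted)


def perturb_genes(sc: SCReference, fraction: float, seed: int = 0) -> SCReference:
    """Shuffle a random ceil(fraction * G) gene subset across cells."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0:
        return sc
    rng = np.random.default_rng(seed)
    G = sc.matrix.n_genes
    n_shuffle = int(np.ceil(fraction * G))
    chosen = rng.choice(G, size=n_shuffle, replace=False)
    vals = sc.matrix.dense()
    for gi in chosen:
        vals[gi] = vals[gi, rng.permutation(vals.shape[1])]
    mat = ExpressionMatrix(vals.astype(sc.matrix.dense().dtype),
                           list(sc.matrix.gene_ids), list(sc.matrix.column_ids), "counts")
    return sc.with_matrix(mat)


def split_reference(sc: SCReference, fraction: float = 0.5,
                    seed: int = 0) -> tuple[SCReference, SCReference]:
    """Random per-type split into disjoint construction/mapping halves."""
    rng = np.random.default_rng(seed)
    first: list[int] = []
    second: list[int] = []
    for t in sc.type_index:
        cols = sc.type_columns(t)
        perm = rng.permutation(cols)
        n1 = int(round(fraction * cols.size))
        first.extend(perm[:n1])
        second.extend(perm[n1:])
    first.sort()
    second.sort()
    return (
        SCReference(sc.matrix.subset_columns(first),
                    [sc.labels[i] for i in first], list(sc.type_index)),
        SCReference(sc.matrix.subset_columns(second),
                    [sc.labels[i] for i in second], list(sc.type_index)),
    )


def _grid_coords(n_spots: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([xs.ravel(), ys.ravel()])[:n_spots].astype(float)


def _domain_profiles(K: int, n_domains: int, purity: float) -> np.ndarray:
    """Mixture profile per domain: dominant type ``purity``, rest uniform."""
    profiles = np.full((n_domains, K), (1.0 - purity) / max(K - 1, 1))
    for d in range(n_domains):
        j = d % K
        profiles[d, j] = purity if K > 1 else 1.0
    return profiles


def simulate_st(sc: SCReference, n_spots: int, lam: float,
                layout: str = "domains",
                template: STDataset | None = None, top_hvg: int = 2000,
                seed: int = 0, n_domains: int | None = None,
                domain_purity: float = DOMAIN_PURITY,
                ) -> tuple[STDataset, SyntheticTruth]:
    """Build a synthetic ST dataset by summing sampled cells per spot.

    Per-spot cell counts are Poisson(``lam``) clamped to >= 1.  In
    ``domains`` layout the grid is partitioned into Voronoi domains (one per
    type by default), each dominated by its own type; in ``template`` layout
    cells are sampled with probability proportional to their Pearson
    correlation (top ``top_hvg`` variable genes) with the template spot, and
    spot coordinates come from the template.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    rng = np.random.default_rng(seed)
    K = sc.n_types
    types = sc.type_index
    type_cols = {t: sc.type_columns(t) for t in types}
    counts_mat = sc.matrix.dense()

    if layout == "domains":
        coords = _grid_coords(n_spots)
        D = n_domains if n_domains is not None else K
        seeds_xy = rng.uniform(coords.min(axis=0), coords.max(axis=0), size=(D, 2))
        d2 = ((coords[:, None, :] - seeds_xy[None, :, :]) ** 2).sum(axis=2)
        domain = d2.argmin(axis=1)
        profiles = _domain_profiles(K, D, domain_purity)
        spot_type_probs = profiles[domain]
    elif layout == "template":
        if template is None:
            raise ValueError("template layout requires a template STDataset")
        coords = template.coords[:n_spots]
        n_spots = coords.shape[0]
        domain = np.zeros(n_spots, dtype=int)
        spot_type_probs = None
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if layout == "template":
        cell_probs = _template_cell_probs(sc, template, top_hvg, n_spots)

    n_cells = np.maximum(rng.poisson(lam, size=n_spots), 1)
    spot_ids = [f"spot{t:05d}" for t in range(n_spots)]
    chosen_cols: list[np.ndarray] = []
    records = []
    type_counts = np.zeros((n_spots, K), dtype=int)
    tindex = {t: j for j, t in enumerate(types)}
    for t_i in range(n_spots):
        c = int(n_cells[t_i])
        if layout == "domains":
            drawn_types = rng.choice(K, size=c, p=spot_type_probs[t_i])
            cols = np.array([rng.choice(type_cols[types[j]]) for j in drawn_types])
        else:
            cols = rng.choice(counts_mat.shape[1], size=c, p=cell_probs[t_i])
        chosen_cols.append(cols)
        for k, col in enumerate(cols):
            ct = sc.labels[int(col)]
            type_counts[t_i, tindex[ct]] += 1
            records.append((f"{spot_ids[t_i]}.cell{k}", sc.cell_ids[int(col)], ct,
                            spot_ids[t_i], coords[t_i, 0], coords[t_i, 1]))
    # spot expression = exact sum of constituent cells' counts
    rows_idx = np.concatenate(chosen_cols)
    cols_idx = np.repeat(np.arange(n_spots), n_cells)
    indicator = sp.coo_matrix(
        (np.ones(rows_idx.size), (rows_idx, cols_idx)),
        shape=(counts_mat.shape[1], n_spots),
    ).tocsr()
    expr = counts_mat @ indicator
    expr = np.asarray(expr.todense()) if sp.issparse(expr) else np.asarray(expr)
    matrix = ExpressionMatrix(expr.astype(np.int64), list(sc.matrix.gene_ids),
                              spot_ids, "counts")
    st = STDataset(matrix, coords)
    truth = SyntheticTruth(
        pd.DataFrame(records, columns=["placed_id", "source_id", "cell_type",
                                       "spot_id", "x", "y"]),
        pd.DataFrame(type_counts, index=spot_ids, columns=types),
        pd.Series(domain, index=spot_ids),
        float(lam),
    )
    return st, truth


def _template_cell_probs(sc: SCReference, template: STDataset, top_hvg: int,
                         n_spots: int) -> np.ndarray:
    """Per-spot sampling probabilities from cell-spot Pearson correlations."""
    shared = [g for g in template.matrix.gene_ids if g in set(sc.matrix.gene_ids)]
    tmat = template.matrix.subset_genes(shared).dense()
    var = tmat.var(axis=1)
    top = np.argsort(var)[::-1][: min(top_hvg, len(shared))]
    genes = [shared[i] for i in np.sort(top)]
    a = sc.matrix.subset_genes(genes).dense().T      # cells x genes
    b = template.matrix.subset_genes(genes).dense().T[:n_spots]  # spots x genes
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.maximum(np.linalg.norm(az, axis=1, keepdims=True), 1e-12)
    bz /= np.maximum(np.linalg.norm(bz, axis=1, keepdims=True), 1e-12)
    pcc = bz @ az.T                                  # spots x cells
    probs = np.clip(pcc, 0.0, None) + 1e-9
    return probs / probs.sum(axis=1, keepdims=True)
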