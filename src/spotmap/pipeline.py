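"""End-to-end orchestration: configuration, the mapping pipeline, and
provenance.

``run_map`` executes the full chain — normalization, marker selection,
spatially weighted likelihood, hotspot detection, spot clustering, robust
deconvolution with hotspot correction, saturation cell counting, candidate
sampling, (optional) classifier pre-assignment, linear assignment, and
coordinate jitter — from in-memory inputs, returning the mapping result and
all intermediate artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assignment as asg
from . import cellcount as cc
from . import deconvolution as dec
from . import hotspot as hs
from . import markers as mk
from . import preprocess as pp
from . import similarity as sim
from .io import MappingResult, SCReference, STDataset, write_mapping

__all__ = ["RunConfig", "PipelineOutput", "run_map"]

log = logging.getLogger("spotmap")


@dataclass
class RunConfig:
    """All pipeline knobs with the method's default values."""

    seed: int = 0
    normalize_method: str = "log_cp_median"
    min_cells: int = 5
    markers_n_top: int = 100
    embed_n_pcs: int = 30
    similarity_probs_quantile: float = 0.3
    similarity_laplace: float = 1e-6
    hotspot_alpha: float = 0.05
    hotspot_knn_spots: int = 5
    cluster_resolution: float = 0.2
    cluster_n_hvg: int = 3000
    deconv_k_smooth: int = 6
    deconv_tau: float = 0.01
    cellcount_n_max: int = 10
    cellcount_min_umi: int = 2
    cellcount_w_L: float = 0.5
    cellcount_quantile: float = 0.90
    platform_res: str = "Low"          # "High" forces one cell per spot
    max_cells_in_spot: int | None = None
    fix_cells_in_spot: bool = True
    fnn_skip_threshold: int = asg.FNN_SKIP_THRESHOLD
    fnn_learning_rate: float = 1e-6

    def __post_init__(self) -> None:
        if self.platform_res not in ("Low", "High"):
            raise ValueError("platform_res must be 'Low' or 'High'")
        if not (0.01 <= self.similarity_probs_quantile <= 1.0):
            raise ValueError("similarity_probs_quantile must lie in [0.01, 1]")
        if not (0.0 < self.hotspot_alpha < 1.0):
            raise ValueError("hotspot_alpha must lie in (0, 1)")

    @property
    def n_max(self) -> int:
        if self.platform_res == "High":
            return 1
        if self.max_cells_in_spot is not None:
            return self.max_cells_in_spot
        return self.cellcount_n_max

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineOutput:
    """Mapping result plus the intermediate artefacts of every stage."""

    result: MappingResult
    markers: mk.MarkerSet
    similarity: sim.SimilarityMatrix
    hotspots: hs.HotspotMatrix
    clusters: pp.SpotClusters
    compositions: dec.CompositionMatrix
    global_composition: pd.Series
    cell_counts: cc.CellCounts
    pool: asg.CandidatePool
    embedding: pp.JointEmbedding


def _subset_st(st: STDataset, spot_ids: list[str]) -> STDataset:
    pos = {s: i for i, s in enumerate(st.spot_ids)}
    idx = [pos[s] for s in spot_ids]
    return STDataset(st.matrix.subset_columns(idx), st.coords[idx])


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-14s %6.2fs", name, t1 - t0)
    return t1


def run_map(sc: SCReference, st: STDataset, config: RunConfig | None = None,
            embedding: pp.JointEmbedding | None = None,
            out_dir: str | Path | None = None) -> PipelineOutput:
    """Run the complete cell-to-spot mapping pipeline.

    ``embedding`` may supply a precomputed joint embedding, bypassing the
    built-in integration.  With ``out_dir`` the mapping, per-spot counts,
    compositions and a provenance record are written to disk.
    """
    cfg = config or RunConfig()
    t0 = time.perf_counter()

    scn = pp.normalize(sc.matrix, cfg.normalize_method)
    stn = pp.normalize(st.matrix, cfg.normalize_method)
    t0 = _stage("normalize", t0)

    spec_table = mk.compute_specificity_table(sc, scn)
    markers = mk.select_markers(sc, spec_table, n_top=cfg.markers_n_top)
    markers = markers.restrict_to(st.matrix.gene_ids)
    if not markers.union:
        raise RuntimeError("markers: no marker gene shared with the ST dataset")
    t0 = _stage("markers", t0)

    if embedding is None:
        embedding = pp.joint_embed(sc, st, markers.union, n_pcs=cfg.embed_n_pcs,
                                   seed=cfg.seed, sc_normalized=scn, st_normalized=stn)
    t0 = _stage("embedding", t0)

    probs = sim.cell_gene_probabilities(sc, markers, normalized=scn,
                                        laplace=cfg.similarity_laplace)
    loglik = sim.log_likelihood(st, probs)
    dw = sim.distance_weights(embedding, cfg.similarity_probs_quantile)
    weighted = sim.weighted_similarity(loglik, dw)
    t0 = _stage("similarity", t0)

    H = hs.hotspot_matrix(st, markers, alpha=cfg.hotspot_alpha,
                          k_neighbors=cfg.hotspot_knn_spots, seed=cfg.seed,
                          normalized=stn)
    t0 = _stage("hotspots", t0)

    clusters = pp.cluster_spots(st, n_hvg=cfg.cluster_n_hvg,
                                resolution=cfg.cluster_resolution,
                                seed=cfg.seed, normalized=stn)
    t0 = _stage("clustering", t0)

    # deconvolution works on the linear library-normalized layer: a spot is a
    # sum of cells only on the linear scale, so regressing log-profiles on a
    # log-basis would misspecify the mixture
    sc_lin = pp.normalize(sc.matrix, "cp_median")
    st_lin = pp.normalize(st.matrix, "cp_median")
    B = dec.build_base_matrix(sc, markers, normalized=sc_lin)
    profiles = dec.smooth_spot_profile(st, clusters, list(B.values.index),
                                       k_smooth=cfg.deconv_k_smooth, normalized=st_lin)
    F = dec.deconvolve_spots(profiles.loc[H.retained_spots], B)
    V = dec.correction_matrix(H, clusters, tau=cfg.deconv_tau)
    F_adj, f_star = dec.adjust_and_aggregate(F, V, clusters, H)
    t0 = _stage("deconvolution", t0)

    st_retained = _subset_st(st, H.retained_spots)
    L, G = cc.spot_summaries(st_retained, min_umi=cfg.cellcount_min_umi)
    L_ref, G_ref = cc.reference_spot(L, G, w_L=cfg.cellcount_w_L,
                                     w_G=1.0 - cfg.cellcount_w_L,
                                     q=cfg.cellcount_quantile)
    counts = cc.estimate_counts(L, G, L_ref, G_ref, n_max=cfg.n_max,
                                spot_ids=H.retained_spots,
                                high_resolution=cfg.platform_res == "High")
    t0 = _stage("cell counts", t0)

    pool = asg.sample_candidates(sc, f_star, counts.total, seed=cfg.seed,
                                 normalized=scn)
    penalized = asg.penalized_similarity(weighted, H, pool)
    t0 = _stage("candidates", t0)

    pre = None
    spot_cluster = None
    if pool.size > cfg.fnn_skip_threshold and clusters.R >= 2:
        clf = asg.train_cluster_classifier(embedding, clusters, seed=cfg.seed,
                                           lr=cfg.fnn_learning_rate)
        spot_pos = {s: i for i, s in enumerate(st.spot_ids)}
        spot_cluster = {s: int(clusters.labels[spot_pos[s]]) for s in H.retained_spots}
        demand: dict[int, int] = {r: 0 for r in range(1, clusters.R + 1)}
        for s in H.retained_spots:
            demand[spot_cluster[s]] += int(counts.counts.loc[s])
        cell_pos = {c: i for i, c in enumerate(sc.cell_ids)}
        cand_pcs = embedding.cell_pcs[[cell_pos[s] for s in pool.source_ids]]
        pre = asg.pre_assign(pool, clf, demand, cand_pcs)
        t0 = _stage("pre-assign", t0)

    A = asg.solve_assignment(penalized, counts, pre=pre, spot_cluster=spot_cluster)
    t0 = _stage("assignment", t0)

    coords_df = pd.DataFrame(st_retained.coords, index=H.retained_spots,
                             columns=["x", "y"])
    result = asg.jitter_coordinates(A, coords_df, pool, counts, seed=cfg.seed,
                                    compositions=F_adj.values,
                                    global_composition=f_star)
    _stage("jitter", t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mapping(result, out_dir / "mapping.tsv")
        markers.to_frame().to_csv(out_dir / "markers.tsv", sep="\t", index=False)
        provenance = {"config": asdict(cfg), "config_digest": cfg.digest(),
                      "n_cells_mapped": result.n_cells,
                      "n_spots_retained": len(H.retained_spots)}
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return PipelineOutput(result, markers, weighted, H, clusters, F_adj,
                          f_star, counts, pool, embedding)
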