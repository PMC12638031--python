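"""Candidate sampling, optional cluster pre-assignment, and cell-to-spot
linear assignment.

The slice-level composition f* and the per-spot counts c* fix how many cells
of each type to draw from the reference (sampling with replacement plus
additive noise when a type runs short).  For large pools, a small
feedforward classifier trained on the spots' PC embedding pre-assigns cells
to ST clusters so the global matching decomposes into per-cluster problems.
Each spot is expanded into c* identical slots and a maximum-weight perfect
matching (Jonker-Volgenant family solver) places every candidate cell in
exactly one slot; assigned cells finally receive uniform jitter inside a
disc of half the minimum inter-spot distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .cellcount import CellCounts
from .hotspot import HotspotMatrix
from .io import ExpressionMatrix, MappingResult, SCReference
from .preprocess import JointEmbedding, SpotClusters
from .similarity import SimilarityMatrix

__all__ = [
    "CandidatePool",
    "ClusterPreAssignment",
    "AssignmentMatrix",
    "largest_remainder",
    "sample_candidates",
    "FeedforwardClassifier",
    "train_cluster_classifier",
    "pre_assign",
    "penalized_similarity",
    "solve_assignment",
    "jitter_coordinates",
]

FNN_SKIP_THRESHOLD = 10_000  # pools at or below this size skip pre-assignment


@dataclass
class CandidatePool:
    """Cells drawn to be placed, with provenance and per-type targets."""

    cell_ids: list[str]          # unique ids (duplicates suffixed)
    source_ids: list[str]        # original SC cell id per candidate
    cell_types: list[str]
    provenance: list[str]        # "original" | "duplicated"
    per_type_target: dict[str, int]
    expression: ExpressionMatrix | None = None  # normalized layer, optional

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.source_ids) == len(self.cell_types) == len(self.provenance) == n):
            raise ValueError("candidate pool fields must align")
        if sum(self.per_type_target.values()) != n:
            raise ValueError("per-type targets must sum to the pool size")

    @property
    def size(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterPreAssignment:
    """Partition of candidate cells over ST clusters with exact demand."""

    assignments: np.ndarray      # cluster id 1..R per candidate
    demand: dict[int, int]

    def __post_init__(self) -> None:
        counts = pd.Series(self.assignments).value_counts().to_dict()
        for r, d in self.demand.items():
            if counts.get(r, 0) != d:
                raise ValueError(f"cluster {r} holds {counts.get(r, 0)} cells, demand {d}")


@dataclass
class AssignmentMatrix:
    """One spot per cell; the inverse map spot -> cells is implied."""

    cell_to_spot: pd.Series      # index: candidate cell id, value: spot id


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``fractions``."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.sum() <= 0:
        raise ValueError("fractions must have positive mass")
    quota = fractions / fractions.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def sample_candidates(sc: SCReference, f_star: pd.Series, total: int, seed: int = 0,
                      normalized: ExpressionMatrix | None = None,
                      with_expression: bool = False) -> CandidatePool:
    """Draw c'_j = largest-remainder(f*_j * total) cells of each type.

    Types with enough cells are sampled without replacement; otherwise with
    replacement, and repeated draws become "duplicated" entries carrying
    additive zero-mean unit-SD noise (clipped at 0) on the normalized layer.
    """
    missing = [t for t, v in f_star.items() if v > 0 and t not in sc.type_index]
    if missing:
        raise ValueError(f"composition names types absent from the reference: {missing}")
    f = f_star.reindex(sc.type_index).fillna(0.0)
    targets = largest_remainder(f.to_numpy(), total)
    rng = np.random.default_rng(seed)
    mat = normalized if normalized is not None else sc.matrix
    ids: list[str] = []
    sources: list[str] = []
    types: list[str] = []
    prov: list[str] = []
    expr_cols: list[np.ndarray] = []
    for t, c_target in zip(sc.type_index, targets):
        if c_target == 0:
            continue
        cols = sc.type_columns(t)
        if cols.size >= c_target:
            chosen = rng.choice(cols, size=c_target, replace=False)
        else:
            # every cell once, remainder re-drawn with replacement
            extra = rng.choice(cols, size=c_target - cols.size, replace=True)
            chosen = np.concatenate([cols, extra])
        seen: dict[int, int] = {}
        for col in chosen:
            col = int(col)
            n_prev = seen.get(col, 0)
            seen[col] = n_prev + 1
            src = sc.cell_ids[col]
            if n_prev == 0:
                ids.append(src)
                prov.append("original")
            else:
                ids.append(f"{src}.dup{n_prev}")
                prov.append("duplicated")
            sources.append(src)
            types.append(t)
            if with_expression:
                vec = mat.values[:, col]
                vec = np.asarray(vec.todense()).ravel() if sp.issparse(vec) else np.asarray(vec).ravel().copy()
                if n_prev > 0:
                    vec = np.clip(vec + rng.standard_normal(vec.size), 0.0, None)
                expr_cols.append(vec)
    expression = None
    if with_expression:
        expression = ExpressionMatrix(
            np.column_stack(expr_cols) if expr_cols else np.zeros((mat.n_genes, 0)),
            list(mat.gene_ids), ids, mat.layer_tag,
        )
    return CandidatePool(ids, sources, types, prov,
                         dict(zip(sc.type_index, targets.tolist())), expression)


# ---------------------------------------------------------------------------
# feedforward cluster classifier
# ---------------------------------------------------------------------------

class FeedforwardClassifier:
    """Small MLP (64-ReLU, 128, 128; dropout 0.2, batchnorm, L2) with softmax.

    Trained with Adam on a 95/5 split of the labeled spots, cross-entropy
    loss plus an L2 penalty, early stopping on held-out loss.
    """

    def __init__(self, n_inputs: int, n_classes: int, hidden=(64, 128, 128),
                 dropout: float = 0.2, l2: float = 0.01, lr: float = 1e-6,
                 seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.l2 = l2
        self.lr = lr
        dims = [n_inputs, *hidden, n_classes]
        self.W = [self.rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                  for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        # batchnorm params per hidden layer
        self.gamma = [np.ones(h) for h in hidden]
        self.beta = [np.zeros(h) for h in hidden]
        self.run_mean = [np.zeros(h) for h in hidden]
        self.run_var = [np.ones(h) for h in hidden]
        self.n_hidden = len(hidden)

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool):
        cache = []
        a = X
        for v in range(self.n_hidden):
            z = a @ self.W[v] + self.b[v]
            if train:
                mu, var = z.mean(axis=0), z.var(axis=0)
                self.run_mean[v] = 0.9 * self.run_mean[v] + 0.1 * mu
                self.run_var[v] = 0.9 * self.run_var[v] + 0.1 * var
            else:
                mu, var = self.run_mean[v], self.run_var[v]
            zhat = (z - mu) / np.sqrt(var + 1e-5)
            h = self.gamma[v] * zhat + self.beta[v]
            h = np.maximum(h, 0.0)
            if train and self.dropout > 0:
                mask = self.rng.random(h.shape) >= self.dropout
                h = h * mask / (1.0 - self.dropout)
            else:
                mask = None
            cache.append((a, z, zhat, mu, var, h, mask))
            a = h
        logits = a @ self.W[-1] + self.b[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return probs

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, max_epochs: int = 500,
            patience: int = 20, val_fraction: float = 0.05,
            batch_size: int = 64) -> "FeedforwardClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        n_classes = self.W[-1].shape[1]
        perm = self.rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx = perm
        Y = np.eye(n_classes)[y]
        # Adam state
        params = self.W + self.b + self.gamma + self.beta
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t_step = 0
        best_loss, best_state, since_best = np.inf, None, 0
        for _epoch in range(max_epochs):
            order = self.rng.permutation(tr_idx)
            for start in range(0, order.size, batch_size):
                batch = order[start:start + batch_size]
                if batch.size < 2:
                    continue
                grads = self._backward(X[batch], Y[batch])
                t_step += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = 0.9 * m[i] + 0.1 * g
                    v[i] = 0.999 * v[i] + 0.001 * g * g
                    mhat = m[i] / (1 - 0.9**t_step)
                    vhat = v[i] / (1 - 0.999**t_step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)
            val_probs = self.predict_proba(X[val_idx])
            val_loss = -np.mean(np.log(val_probs[np.arange(val_idx.size), y[val_idx]] + 1e-12))
            if val_loss < best_loss - 1e-6:
                best_loss, since_best = val_loss, 0
                best_state = [p.copy() for p in params]
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_state is not None:
            for p, s in zip(params, best_state):
                p[...] = s
        return self

    def _backward(self, X: np.ndarray, Y: np.ndarray):
        probs, cache = self._forward(X, train=True)
        n = X.shape[0]
        dW = [np.zeros_like(w) for w in self.W]
        db = [np.zeros_like(b) for b in self.b]
        dgamma = [np.zeros_like(g) for g in self.gamma]
        dbeta = [np.zeros_like(b) for b in self.beta]
        delta = (probs - Y) / n
        a_last = cache[-1][5]
        dW[-1] = a_last.T @ delta + self.l2 * self.W[-1]
        db[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for vli in range(self.n_hidden - 1, -1, -1):
            a_in, z, zhat, mu, var, h, mask = cache[vli]
            if mask is not None:
                da = da * mask / (1.0 - self.dropout)
            dh = da * (h > 0)
            dgamma[vli] = (dh * zhat).sum(axis=0)
            dbeta[vli] = dh.sum(axis=0)
            dzhat = dh * self.gamma[vli]
            inv = 1.0 / np.sqrt(var + 1e-5)
            nb = z.shape[0]
            dz = (inv / nb) * (nb * dzhat - dzhat.sum(axis=0)
                               - zhat * (dzhat * zhat).sum(axis=0))
            dW[vli] = a_in.T @ dz + self.l2 * self.W[vli]
            db[vli] = dz.sum(axis=0)
            da = dz @ self.W[vli].T
        return dW + db + dgamma + dbeta


class _IdentityClassifier:
    """Single-cluster degenerate case: everything belongs to cluster 1."""

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.ones((np.asarray(X).shape[0], 1))


def train_cluster_classifier(embed: JointEmbedding, clusters: SpotClusters,
                             seed: int = 0, lr: float = 1e-6,
                             max_epochs: int = 500, patience: int = 20):
    """Train the cluster classifier on the spots' PC coordinates."""
    if clusters.R < 2:
        return _IdentityClassifier()
    X = embed.spot_pcs
    y = clusters.labels - 1
    clf = FeedforwardClassifier(X.shape[1], clusters.R, lr=lr, seed=seed)
    return clf.fit(X, y, max_epochs=max_epochs, patience=patience)


def pre_assign(pool: CandidatePool, classifier, demand: dict[int, int],
               cell_pcs: np.ndarray) -> ClusterPreAssignment:
    """Partition candidates over clusters to match per-cluster demand exactly.

    Cells start at their argmax-probability cluster; while any cluster is
    over capacity, its lowest-margin cells (smallest drop from their current
    probability to the best under-capacity alternative) move there.  Each
    move reduces total surplus by one, so the loop terminates.
    """
    if sum(demand.values()) != pool.size:
        raise ValueError("total demand must equal the pool size")
    probs = classifier.predict_proba(cell_pcs)
    cluster_ids = sorted(demand)
    if probs.shape[1] != len(cluster_ids):
        raise ValueError("classifier output does not match the demand clusters")
    col = {r: i for i, r in enumerate(cluster_ids)}
    assign = np.array([cluster_ids[i] for i in probs.argmax(axis=1)])
    counts = {r: int((assign == r).sum()) for r in cluster_ids}
    while True:
        over = sorted((r for r in cluster_ids if counts[r] > demand[r]),
                      key=lambda r: (-(counts[r] - demand[r]), r))
        if not over:
            break
        r = over[0]
        under = [u for u in cluster_ids if counts[u] < demand[u]]
        members = np.flatnonzero(assign == r)
        # margin: current-cluster probability minus best under-capacity probability
        alt = probs[np.ix_(members, [col[u] for u in under])]
        best_alt = alt.argmax(axis=1)
        margin = probs[members, col[r]] - alt[np.arange(members.size), best_alt]
        mover = members[int(np.argmin(margin))]
        dest = under[int(best_alt[int(np.argmin(margin))])]
        assign[mover] = dest
        counts[r] -= 1
        counts[dest] += 1
    return ClusterPreAssignment(assign, dict(demand))


def penalized_similarity(sim: SimilarityMatrix, H: HotspotMatrix,
                         pool: CandidatePool) -> SimilarityMatrix:
    """P** = P' - (1 - H') on retained spots x candidate cells.

    Each candidate inherits its source cell's similarity column; pairs whose
    spot is not a hotspot for the candidate's type lose a full unit, pushing
    them below every hotspot-consistent pair.
    """
    col = {c: i for i, c in enumerate(sim.col_ids)}
    row = {s: i for i, s in enumerate(sim.row_ids)}
    retained = H.retained_spots
    r_idx = np.array([row[s] for s in retained])
    c_idx = np.array([col[src] for src in pool.source_ids])
    values = sim.values[np.ix_(r_idx, c_idx)].copy()
    Hv = H.values.loc[retained]
    type_cols = np.array([Hv.columns.get_loc(t) for t in pool.cell_types])
    hot = Hv.to_numpy()[:, type_cols].astype(float)
    return SimilarityMatrix(values - (1.0 - hot), list(retained), list(pool.cell_ids))


def solve_assignment(sim: SimilarityMatrix, counts: CellCounts,
                     pre: ClusterPreAssignment | None = None,
                     clusters: SpotClusters | None = None,
                     spot_cluster: dict[str, int] | None = None) -> AssignmentMatrix:
    """Maximum-weight perfect matching of candidate cells to spot slots.

    Every spot contributes c*_t identical slots.  With a pre-assignment, the
    matching is solved independently per ST cluster; otherwise globally.
    Raises if any subproblem's cell and slot totals disagree.
    """
    spot_ids = sim.row_ids
    cell_ids = np.asarray(sim.col_ids)
    c = counts.counts
    if pre is None:
        groups = {0: (np.arange(len(spot_ids)), np.arange(len(cell_ids)))}
    else:
        if spot_cluster is None:
            raise ValueError("per-cluster solving needs a spot -> cluster map")
        groups = {}
        for r in sorted(pre.demand):
            rows = np.array([i for i, s in enumerate(spot_ids) if spot_cluster[s] == r], dtype=int)
            cols = np.flatnonzero(pre.assignments == r)
            groups[r] = (rows, cols)
    mapping: dict[str, str] = {}
    for r, (rows, cols) in groups.items():
        slots: list[int] = []
        for i in rows:
            slots.extend([i] * int(c.loc[spot_ids[i]]))
        if len(slots) != cols.size:
            raise ValueError(
                f"cluster {r}: {cols.size} cells but {len(slots)} slots"
            )
        if not slots:
            continue
        cost = sim.values[np.ix_(np.asarray(slots), cols)]
        ri, ci = linear_sum_assignment(cost, maximize=True)
        for slot_pos, cell_pos in zip(ri, ci):
            mapping[cell_ids[cols[cell_pos]]] = spot_ids[slots[slot_pos]]
    return AssignmentMatrix(pd.Series(mapping, name="spot_id"))


def jitter_coordinates(A: AssignmentMatrix, spot_coords: pd.DataFrame,
                       pool: CandidatePool, counts: CellCounts,
                       seed: int = 0,
                       compositions: pd.DataFrame | None = None,
                       global_composition: pd.Series | None = None) -> MappingResult:
    """Place each assigned cell uniformly inside a disc around its spot.

    The disc radius is half the minimum pairwise spot distance (1.0 with a
    single spot).  Uniformity comes from r * sqrt(u) radial sampling.
    """
    xy = spot_coords[["x", "y"]]
    if len(xy) >= 2:
        radius = 0.5 * float(pdist(xy.to_numpy()).min())
    else:
        warnings.warn("single spot; jitter radius defaults to 1.0")
        radius = 1.0
    rng = np.random.default_rng(seed)
    ptype = dict(zip(pool.cell_ids, pool.cell_types))
    rows = []
    for cell_id, spot_id in A.cell_to_spot.items():
        cx, cy = xy.loc[spot_id]
        rr = radius * np.sqrt(rng.random())
        th = 2 * np.pi * rng.random()
        rows.append((cell_id, ptype[cell_id], spot_id,
                     float(cx + rr * np.cos(th)), float(cy + rr * np.sin(th))))
    records = pd.DataFrame(rows, columns=list(MappingResult.COLUMNS))
    per_spot = {s: int(v) for s, v in counts.counts.items()}
    return MappingResult(records, per_spot, compositions, global_composition)
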