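import itertools

import numpy as np
import pandas as pd
import pytest

import spotmap
from spotmap.assignment import (
    FeedforwardClassifier,
    largest_remainder,
    jitter_coordinates,
    penalized_similarity,
    pre_assign,
    sample_candidates,
    solve_assignment,
    train_cluster_classifier,
    AssignmentMatrix,
    CandidatePool,
    ClusterPreAssignment,
)
from spotmap.cellcount import CellCounts
from spotmap.hotspot import HotspotMatrix
from spotmap.preprocess import JointEmbedding, SpotClusters
from spotmap.similarity import SimilarityMatrix


@pytest.mark.parametrize("fracs,total", [
    ([1.0, 0.0], 7), ([0.3, 0.3, 0.4], 10), ([0.51, 0.49], 3),
    ([0.2] * 5, 13),
])
def test_largest_remainder_conserves_total(fracs, total):
    parts = largest_remainder(np.array(fracs), total)
    assert parts.sum() == total
    assert (parts >= 0).all()
    assert parts[np.argmax(fracs)] >= parts[np.argmin(fracs)]


def test_sampling_respects_targets_and_flags_duplicates(small_sc):
    sc, _ = small_sc
    f = pd.Series([1.0, 0.0, 0.0], index=sc.type_index)
    pool = sample_candidates(sc, f, total=7, seed=0)
    assert pool.size == 7
    assert set(pool.cell_types) == {sc.type_index[0]}

    # request more cells than the type holds -> duplicates flagged
    f_all = pd.Series([1.0, 0.0, 0.0], index=sc.type_index)
    n_have = len(sc.type_columns(sc.type_index[0]))
    pool2 = sample_candidates(sc, f_all, total=n_have + 2, seed=0,
                              with_expression=True)
    assert pool2.provenance.count("duplicated") == 2
    assert len(set(pool2.cell_ids)) == pool2.size  # ids stay unique
    assert (pool2.expression.dense() >= 0).all()   # noise clipped at 0


def test_sampling_unknown_type_rejected(small_sc):
    sc, _ = small_sc
    f = pd.Series([0.5, 0.5], index=["nope", sc.type_index[0]])
    with pytest.raises(ValueError, match="absent"):
        sample_candidates(sc, f, total=4, seed=0)


def test_classifier_learns_separable_clusters_and_is_deterministic():
    rng = np.random.default_rng(3)
    n = 400
    X = np.vstack([rng.normal(-3, 0.5, size=(n // 2, 5)),
                   rng.normal(3, 0.5, size=(n // 2, 5))])
    y = np.repeat([0, 1], n // 2)
    clf = FeedforwardClassifier(5, 2, lr=1e-2, seed=0).fit(X, y, max_epochs=100)
    probs = clf.predict_proba(X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert (probs.argmax(axis=1) == y).mean() >= 0.95

    clf2 = FeedforwardClassifier(5, 2, lr=1e-2, seed=0).fit(X, y, max_epochs=100)
    np.testing.assert_allclose(probs, clf2.predict_proba(X))


def test_single_cluster_identity_classifier():
    embed = JointEmbedding(np.zeros((3, 2)), np.zeros((4, 2)),
                           np.zeros((3, 5)), np.zeros((4, 5)))
    clf = train_cluster_classifier(embed, SpotClusters(np.ones(4, dtype=int), 1))
    np.testing.assert_allclose(clf.predict_proba(np.zeros((3, 5))), 1.0)


def _pool(n, types=None):
    ids = [f"c{i}" for i in range(n)]
    tys = types or ["T0"] * n
    return CandidatePool(ids, ids, tys, ["original"] * n, {t: tys.count(t) for t in set(tys)})


class _FixedProbs:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return self.probs


def test_pre_assign_no_moves_when_demand_matches():
    probs = [[0.9, 0.1], [0.8, 0.2], [0.2, 0.8]]
    pre = pre_assign(_pool(3), _FixedProbs(probs), {1: 2, 2: 1}, np.zeros((3, 2)))
    np.testing.assert_array_equal(pre.assignments, [1, 1, 2])


def test_pre_assign_moves_lowest_margin_cell():
    # all prefer cluster 1, demand (2, 1): exactly the weakest preference moves
    probs = [[0.9, 0.1], [0.6, 0.4], [0.95, 0.05]]
    pre = pre_assign(_pool(3), _FixedProbs(probs), {1: 2, 2: 1}, np.zeros((3, 2)))
    np.testing.assert_array_equal(pre.assignments, [1, 2, 1])


def test_pre_assign_outputs_exact_partition(rng):
    n, R = 60, 4
    probs = rng.dirichlet(np.ones(R), size=n)
    demand = {r + 1: 15 for r in range(R)}
    pre = pre_assign(_pool(n), _FixedProbs(probs), demand, np.zeros((n, R)))
    counts = pd.Series(pre.assignments).value_counts()
    assert all(counts[r] == 15 for r in demand)


def _hotspots(spot_ids, types, values):
    df = pd.DataFrame(values, index=spot_ids, columns=types).astype(bool)
    return HotspotMatrix(df, list(df.index[df.any(axis=1)]))


def test_penalized_similarity_subtracts_one_off_hotspot():
    sim = SimilarityMatrix(np.array([[0.8, 0.4]]), ["s0"], ["c0", "c1"])
    H = _hotspots(["s0"], ["A", "B"], [[True, False]])
    pool = CandidatePool(["c0", "c1"], ["c0", "c1"], ["A", "B"],
                         ["original"] * 2, {"A": 1, "B": 1})
    out = penalized_similarity(sim, H, pool)
    assert out.values[0, 0] == pytest.approx(0.8)    # hotspot pair unchanged
    assert out.values[0, 1] == pytest.approx(-0.6)   # 0.4 - 1
    assert out.values.min() >= -1.0


def _counts(spot_ids, values, n_max=10):
    return CellCounts(pd.Series(values, index=spot_ids),
                      np.ones(len(values)), np.ones(len(values)),
                      {}, n_max)


def test_assignment_identity_on_diagonal_similarity():
    sim = SimilarityMatrix(np.eye(2), ["s0", "s1"], ["c0", "c1"])
    A = solve_assignment(sim, _counts(["s0", "s1"], [1, 1]))
    assert A.cell_to_spot["c0"] == "s0" and A.cell_to_spot["c1"] == "s1"


@pytest.mark.parametrize("seed", range(10))
def test_assignment_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    sim = SimilarityMatrix(rng.normal(size=(n, n)),
                           [f"s{i}" for i in range(n)], [f"c{i}" for i in range(n)])
    A = solve_assignment(sim, _counts([f"s{i}" for i in range(n)], [1] * n))
    spot_pos = {s: i for i, s in enumerate(sim.row_ids)}
    got = sum(sim.values[spot_pos[A.cell_to_spot[f"c{j}"]], j] for j in range(n))
    best = max(sum(sim.values[perm[j], j] for j in range(n))
               for perm in itertools.permutations(range(n)))
    assert got == pytest.approx(best)


def test_slot_expansion_gives_capacity_two():
    sim = SimilarityMatrix(np.array([[1.0, 0.9, 0.1], [0.2, 0.1, 0.9]]),
                           ["big", "small"], ["c0", "c1", "c2"])
    A = solve_assignment(sim, _counts(["big", "small"], [2, 1]))
    placed = pd.Series(A.cell_to_spot).value_counts()
    assert placed["big"] == 2 and placed["small"] == 1


def test_assignment_count_mismatch_raises():
    sim = SimilarityMatrix(np.ones((1, 3)), ["s0"], ["c0", "c1", "c2"])
    with pytest.raises(ValueError, match="slots"):
        solve_assignment(sim, _counts(["s0"], [2]))


def test_jitter_radius_uniformity_and_determinism():
    coords = pd.DataFrame({"x": [0.0, 2.0], "y": [0.0, 0.0]}, index=["s0", "s1"])
    n = 10_000
    ids = [f"c{i}" for i in range(n + 1)]
    pool = CandidatePool(ids, ids, ["T0"] * (n + 1), ["original"] * (n + 1),
                         {"T0": n + 1})
    targets = {i: "s0" for i in ids[:n]}
    targets[ids[n]] = "s1"
    A = AssignmentMatrix(pd.Series(targets))
    counts = _counts(["s0", "s1"], [n, 1], n_max=n)
    res = jitter_coordinates(A, coords, pool, counts, seed=5)
    r = 1.0  # half the minimum spot distance
    on_s0 = res.records[res.records["spot_id"] == "s0"]
    d2 = on_s0["x"] ** 2 + on_s0["y"] ** 2
    assert (d2 <= r**2 + 1e-12).all()
    # uniform disc: E[d^2] = r^2 / 2
    assert d2.mean() == pytest.approx(r**2 / 2, rel=0.03)
    res2 = jitter_coordinates(A, coords, pool, counts, seed=5)
    pd.testing.assert_frame_equal(res.records, res2.records)


def test_end_to_end_conservation_and_hotspot_discipline(pipeline_run):
    out = pipeline_run
    assert out.result.n_cells == out.cell_counts.total
    # each retained spot receives exactly its estimated number of cells
    placed = out.result.cells_per_spot()
    for spot, c in out.cell_counts.counts.items():
        assert placed.get(spot, 0) == c
    # cells overwhelmingly land on hotspot spots of their own type
    H = out.hotspots.values
    ok = sum(bool(H.loc[row.spot_id, row.cell_type])
             for row in out.result.records.itertuples())
    assert ok / out.result.n_cells > 0.95
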