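import numpy as np
import pandas as pd
import pytest

import spotmap
from spotmap import metrics as mx
from spotmap.io import ExpressionMatrix, MappingResult, STDataset


def _counts(rows, types=("A", "B")):
    return pd.DataFrame(rows, columns=list(types),
                        index=[f"s{i}" for i in range(len(rows))])


def test_accuracy_index_perfect_prediction_is_one():
    t = _counts([[2, 0], [0, 3], [1, 1]])
    out = mx.accuracy_index(t, t)
    np.testing.assert_allclose(out.to_numpy(), 1.0)


def test_accuracy_index_all_cells_in_wrong_spots_is_zero():
    true = _counts([[0, 1], [2, 1]])
    pred = _counts([[5, 1], [0, 1]])  # all A cells in the true-zero spot
    assert mx.accuracy_index(pred, true)["A"] == 0.0


def test_accuracy_index_hand_computed_both_variants():
    true = _counts([[1], [1]], types=("A",))
    pred = _counts([[2], [0]], types=("A",))
    a = 2 / 2                      # all predicted cells are in true-positive spots
    rmse = np.sqrt(((2 - 1) ** 2 + (0 - 1) ** 2) / 2)  # = 1
    harmonic = mx.accuracy_index(pred, true, "harmonic")["A"]
    b = max(0.0, 1 - rmse)         # = 0
    assert harmonic == pytest.approx(0.0 if a + b == 0 else 2 * a * b / (a + b))
    literal = mx.accuracy_index(pred, true, "literal")["A"]
    assert literal == np.inf       # printed form diverges at RMSE = 1


def test_hvg_conservation_formula():
    assert mx.hvg_conservation({"a", "b"}, {"a", "b"}) == 1.0
    assert mx.hvg_conservation({"a"}, {"b"}) == 0.0
    a = {f"g{i}" for i in range(500)}
    b = {f"g{i}" for i in range(250, 750)}
    assert mx.hvg_conservation(a, b) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        mx.hvg_conservation(set(), {"a"})


def test_spot_jaccard_cases():
    a = {"s1": {"A", "B"}, "s2": {"A"}, "s3": set()}
    b = {"s1": {"B", "C"}, "s2": {"A"}, "s3": set()}
    with pytest.warns(UserWarning, match="empty on both"):
        out = mx.spot_jaccard(a, b)
    assert out["s1"] == pytest.approx(1 / 3)
    assert out["s2"] == 1.0
    assert out["s3"] == 1.0  # flagged convention


def test_composition_concordance_identity_and_reproducibility(small_st):
    _, truth = small_st
    pcc, rmse = mx.composition_concordance(truth.type_counts, truth,
                                           n_spots=100, n_iter=10, seed=0)
    np.testing.assert_allclose(pcc, 1.0, atol=1e-12)
    np.testing.assert_allclose(rmse, 0.0, atol=1e-12)
    p2, r2 = mx.composition_concordance(truth.type_counts, truth,
                                        n_spots=100, n_iter=10, seed=0)
    np.testing.assert_array_equal(pcc, p2)


def test_composition_rmse_hand_value():
    truth_counts = _counts([[8, 0], [0, 2]])

    class _T:
        type_counts = truth_counts

    pred = _counts([[5, 0], [0, 5]])
    _, rmse = mx.composition_concordance(pred, _T(), n_spots=2, n_iter=1, seed=0)
    # true proportions (0.8, 0.2), predicted (0.5, 0.5) -> RMSE = 0.3
    assert rmse[0] == pytest.approx(0.3)


def _mapping(records):
    return MappingResult(
        pd.DataFrame(records, columns=list(MappingResult.COLUMNS)),
        {},
    )


def test_expression_recovery_identity_and_orthogonal():
    st_vals = np.array([[3.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    st = STDataset(ExpressionMatrix(st_vals, ["g1", "g2", "g3"], ["s0", "s1"]),
                   np.array([[0.0, 0.0], [1.0, 0.0]]))
    pool = ExpressionMatrix(st_vals.copy(), ["g1", "g2", "g3"], ["c0", "c1"],
                            "normalized")
    identity = _mapping([("c0", "T", "s0", 0, 0), ("c1", "T", "s1", 1, 0)])
    assert mx.expression_recovery(identity, pool, st, n_hvg=3) == pytest.approx(1.0)
    swapped = _mapping([("c0", "T", "s1", 1, 0), ("c1", "T", "s0", 0, 0)])
    assert mx.expression_recovery(swapped, pool, st, n_hvg=3) == pytest.approx(0.0)


def brute_force_kl(true_pts, mapped_pts, grid, h):
    def dens(points):
        out = []
        for g in grid:
            total = 0.0
            for p in points:
                total += np.exp(-((g[0] - p[0]) ** 2 + (g[1] - p[1]) ** 2) / (2 * h * h))
            out.append(max(total, 1e-12))
        out = np.array(out)
        return out / out.sum()

    pt, pm = dens(true_pts), dens(mapped_pts)
    return float(np.sum(pt * np.log(pt / pm)))


def test_kl_spatial_identity_nonnegative_and_oracle(rng):
    pts_a = rng.normal(0, 1, size=(30, 2))
    pts_b = rng.normal(2, 1, size=(30, 2))
    frame_a = pd.DataFrame({"cell_type": "A", "x": pts_a[:, 0], "y": pts_a[:, 1]})
    frame_b = pd.DataFrame({"cell_type": "A", "x": pts_b[:, 0], "y": pts_b[:, 1]})
    same = mx.kl_spatial(frame_a, frame_a, bandwidth=0.5, grid_n=10)
    assert same["A"] == pytest.approx(0.0, abs=1e-12)
    kl = mx.kl_spatial(frame_b, frame_a, bandwidth=0.5, grid_n=10)
    assert kl["A"] >= 0

    all_xy = np.vstack([pts_a, pts_b])
    lo, hi = all_xy.min(axis=0), all_xy.max(axis=0)
    grid = np.array([(x, y) for x in np.linspace(lo[0], hi[0], 10)
                     for y in np.linspace(lo[1], hi[1], 10)])
    oracle = brute_force_kl(pts_a, pts_b, grid, 0.5)
    assert kl["A"] == pytest.approx(oracle, abs=1e-6)


def test_kl_spatial_missing_type_is_infinite(rng):
    a = pd.DataFrame({"cell_type": "A", "x": rng.random(6), "y": rng.random(6)})
    b = pd.DataFrame({"cell_type": "B", "x": rng.random(6), "y": rng.random(6)})
    with pytest.warns(UserWarning, match="missing"):
        out = mx.kl_spatial(a, b, bandwidth=0.5)
    assert np.isinf(out["A"]) and np.isinf(out["B"])


def test_coexistence_index_cases():
    rec = []
    for s in ("s1", "s2", "s3", "s4"):
        rec.append((f"i{s}", "I", s, 0, 0))      # I in 4 spots
    rec += [("j1", "J", "s1", 0, 0), ("j2", "J", "s2", 0, 0)]  # J in 2 spots
    rec += [("k1", "K", "s1", 0, 0)]             # K only with I and J
    out = mx.coexistence(_mapping(rec))
    assert out.loc["I", "J"] == pytest.approx(1.0)   # J fully inside I
    assert out.loc["K", "K"] == 1.0
    pd.testing.assert_frame_equal(out, out.T)        # symmetric
    rec2 = [("a", "A", "s1", 0, 0), ("b", "B", "s2", 0, 0)]
    assert mx.coexistence(_mapping(rec2)).loc["A", "B"] == 0.0


def test_coexistence_partial_overlap():
    rec = [(f"i{k}", "I", f"s{k}", 0, 0) for k in range(4)]
    rec += [("j0", "J", "s0", 0, 0), ("j9", "J", "s9", 0, 0)]
    out = mx.coexistence(_mapping(rec))
    # |S_I| = 4, |S_J| = 2, overlap 1 -> 0.5
    assert out.loc["I", "J"] == pytest.approx(0.5)


def test_sgma_extremes(small_sc, small_st):
    sc, _ = small_sc
    st, truth = small_st
    true_sets = truth.type_spot_sets()
    val_true, per = mx.sgma(true_sets, st, sc, seed=0)
    spots = set(st.spot_ids)
    complement = {t: spots - s for t, s in true_sets.items()}
    val_comp, _ = mx.sgma(complement, st, sc, seed=0)
    assert val_true > val_comp
    assert 0.0 <= val_true <= 1.0 and 0.0 <= val_comp <= 1.0
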