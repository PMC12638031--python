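import numpy as np
import pandas as pd
import pytest

from spotmap.deconvolution import (
    BaseMatrix,
    CompositionMatrix,
    CorrectionMatrix,
    adjust_and_aggregate,
    build_base_matrix,
    correction_matrix,
    rlm_deconvolve,
    smooth_spot_profile,
)
from spotmap.hotspot import HotspotMatrix
from spotmap.io import ExpressionMatrix, SCReference, STDataset
from spotmap.markers import MarkerSet
from spotmap.preprocess import SpotClusters


def test_base_matrix_one_cell_per_type_equals_columns():
    vals = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
    mat = ExpressionMatrix(vals, ["g1", "g2", "g3"], ["a", "b"], "normalized")
    sc = SCReference(ExpressionMatrix(vals, ["g1", "g2", "g3"], ["a", "b"]),
                     ["T0", "T1"], ["T0", "T1"])
    ms = MarkerSet({"T0": ["g3", "g1"], "T1": ["g2"]})
    B = build_base_matrix(sc, ms, normalized=mat)
    assert list(B.values.index) == ["g3", "g1", "g2"]  # marker union order
    np.testing.assert_allclose(B.values.to_numpy(), vals[[2, 0, 1]])


def test_base_matrix_planted_two_type_mean():
    vals = np.array([[1.0, 3.0, 10.0], [0.0, 2.0, 4.0]])
    mat = ExpressionMatrix(vals, ["g1", "g2"], ["a", "b", "c"], "normalized")
    sc = SCReference(ExpressionMatrix(vals, ["g1", "g2"], ["a", "b", "c"]),
                     ["T0", "T0", "T1"], ["T0", "T1"])
    B = build_base_matrix(sc, MarkerSet({"T0": ["g1"], "T1": ["g2"]}), normalized=mat)
    np.testing.assert_allclose(B.values.to_numpy(), [[2.0, 10.0], [1.0, 4.0]])


def _line_st(values):
    n = len(values)
    x = np.tile(np.asarray(values, dtype=float), (2, 1))
    mat = ExpressionMatrix(x + 1, ["g1", "g2"], [f"s{i}" for i in range(n)],
                           "normalized")
    coords = np.column_stack([np.arange(n), np.zeros(n)]).astype(float)
    raw = ExpressionMatrix(np.ones((2, n)), ["g1", "g2"], [f"s{i}" for i in range(n)])
    return STDataset(raw, coords), mat


def test_smoothing_identity_cases():
    st, mat = _line_st([0.0, 3.0, 6.0])
    clusters = SpotClusters(np.ones(3, dtype=int), 1)
    out1 = smooth_spot_profile(st, clusters, ["g1", "g2"], k_smooth=1, normalized=mat)
    np.testing.assert_allclose(out1.to_numpy(), mat.dense().T)
    out3 = smooth_spot_profile(st, clusters, ["g1", "g2"], k_smooth=3, normalized=mat)
    np.testing.assert_allclose(out3.to_numpy(), 4.0)  # (1+4+7)/3 everywhere


def test_smoothing_respects_cluster_boundaries():
    st, mat = _line_st([0.0, 0.0, 9.0, 9.0])
    clusters = SpotClusters(np.array([1, 1, 2, 2]), 2)
    out = smooth_spot_profile(st, clusters, ["g1", "g2"], k_smooth=4, normalized=mat)
    np.testing.assert_allclose(out.to_numpy()[:2], 1.0)
    np.testing.assert_allclose(out.to_numpy()[2:], 10.0)


def _random_base(rng, m=200, K=5):
    B = rng.gamma(2.0, 2.0, size=(m, K))
    return pd.DataFrame(B, index=[f"g{i}" for i in range(m)],
                        columns=[f"T{j}" for j in range(K)])


def test_rlm_exact_recovery_and_indicator(rng):
    B = _random_base(rng, m=50, K=2)
    f = np.array([0.3, 0.7])
    y = B.to_numpy() @ f
    np.testing.assert_allclose(rlm_deconvolve(y, B), f, atol=1e-6)
    e1 = rlm_deconvolve(B.to_numpy()[:, 1], B)
    np.testing.assert_allclose(e1, [0.0, 1.0], atol=1e-8)


def grid_search_two_type(y, B, step=1e-3):
    """Dense oracle for K=2: minimize ||y - B f|| over the simplex."""
    best, best_err = None, np.inf
    for f1 in np.arange(0.0, 1.0 + step, step):
        f = np.array([f1, 1.0 - f1])
        err = np.sum((y - B @ f) ** 2)
        if err < best_err:
            best, best_err = f, err
    return best


def test_rlm_noisy_recovery_matches_grid_oracle(rng):
    B5 = _random_base(rng, m=200, K=5)
    truth = rng.dirichlet(np.ones(5), size=20)
    errs = []
    for f in truth:
        y = B5.to_numpy() @ f + rng.normal(0, 0.05 * B5.to_numpy().mean(), size=200)
        est = rlm_deconvolve(np.clip(y, 0, None), B5)
        errs.append(np.abs(est - f).mean())
    assert np.mean(errs) < 0.05

    B2 = _random_base(rng, m=100, K=2)
    for f1 in (0.2, 0.5, 0.9):
        f = np.array([f1, 1 - f1])
        y = B2.to_numpy() @ f + rng.normal(0, 0.05 * B2.to_numpy().mean(), size=100)
        est = rlm_deconvolve(np.clip(y, 0, None), B2)
        oracle = grid_search_two_type(y, B2.to_numpy())
        np.testing.assert_allclose(est, oracle, atol=0.02)


def _H(spot_ids, types, values):
    df = pd.DataFrame(values, index=spot_ids, columns=types).astype(bool)
    return HotspotMatrix(df, list(df.index[df.any(axis=1)]))


def test_correction_matrix_rescale_and_binarize():
    spots = [f"s{i}" for i in range(15)]
    # cluster 1: counts per type (0, 5, 10)
    vals = np.zeros((15, 3), dtype=bool)
    vals[:5, 1] = True
    vals[5:15, 2] = True
    H = _H(spots, ["A", "B", "C"], vals)
    clusters = SpotClusters(np.ones(15, dtype=int), 1)
    V = correction_matrix(H, clusters, tau=0.01)
    np.testing.assert_array_equal(V.values.to_numpy()[0], [0.0, 1.0, 1.0])


def test_correction_matrix_empty_cluster_keeps_all_types():
    spots = ["s0", "s1", "s2", "s3"]
    vals = np.array([[1, 0], [1, 0], [0, 0], [0, 0]], dtype=bool)
    H = HotspotMatrix(pd.DataFrame(vals, index=spots, columns=["A", "B"]),
                      ["s0", "s1"])
    clusters = SpotClusters(np.array([1, 1, 2, 2]), 2)
    with pytest.warns(UserWarning, match="no hotspot evidence"):
        V = correction_matrix(H, clusters)
    np.testing.assert_array_equal(V.values.to_numpy()[1], [1.0, 1.0])


def test_adjustment_identity_zeroing_and_aggregation():
    spots = ["s0", "s1"]
    F = CompositionMatrix(pd.DataFrame([[0.5, 0.5], [0.2, 0.8]], index=spots,
                                       columns=["A", "B"]), [])
    H = _H(spots, ["A", "B"], np.ones((2, 2), dtype=bool))
    clusters = SpotClusters(np.array([1, 1]), 1)
    V1 = CorrectionMatrix(pd.DataFrame([[1.0, 1.0]], index=[1], columns=["A", "B"]))
    adj, fstar = adjust_and_aggregate(F, V1, clusters, H)
    np.testing.assert_allclose(adj.values.to_numpy(), F.values.to_numpy())
    assert fstar.sum() == pytest.approx(1.0)

    V0 = CorrectionMatrix(pd.DataFrame([[1.0, 0.0]], index=[1], columns=["A", "B"]))
    adj0, fstar0 = adjust_and_aggregate(F, V0, clusters, H)
    np.testing.assert_allclose(adj0.values.loc["s0"].to_numpy(), [1.0, 0.0])
    # support never grows
    assert (adj0.values.to_numpy() > 0).sum() <= (F.values.to_numpy() > 0).sum()
    assert fstar0.sum() == pytest.approx(1.0)
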