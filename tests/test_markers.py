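import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

import spotmap
from spotmap.io import ExpressionMatrix
from spotmap.markers import (
    compute_specificity_table,
    gene_weights,
    mean_expression_by_type,
    select_markers,
    specificity_scores,
)
from spotmap.preprocess import normalize


def test_gene_weights_direct_formula():
    meanX = pd.DataFrame(
        {"A": [2.0, 1.0, 10.0], "B": [1.0, 5.0, 3.0]},
        index=["g_lo", "g_mid", "g_hi"],
    )  # row maxima: 2, 5, 10
    w = gene_weights(meanX)
    assert w["g_hi"] == 1.0          # attains the global maximum
    assert w["g_lo"] == 0.0          # row-max equals the min of row-maxima
    assert w["g_mid"] == pytest.approx((5 - 2) / (10 - 2))


def test_constant_mean_matrix_weights_all_one():
    meanX = pd.DataFrame(np.full((3, 2), 4.0), index=list("abc"), columns=["A", "B"])
    with pytest.warns(UserWarning, match="constant"):
        w = gene_weights(meanX)
    assert (w == 1.0).all()


def test_specificity_uniform_gene_scores_zero():
    meanX = pd.DataFrame(np.full((1, 4), 3.0), index=["g"], columns=list("ABCD"))
    spec = specificity_scores(meanX, pd.Series([1.0], index=["g"]), K=4)
    assert spec["g"] == pytest.approx(0.0, abs=1e-12)


def test_specificity_exclusive_gene_attains_entropy_bound():
    meanX = pd.DataFrame([[8.0, 0.0, 0.0, 0.0]], index=["g"], columns=list("ABCD"))
    spec = specificity_scores(meanX, pd.Series([1.0], index=["g"]), K=4)
    # exclusive expression: (1/K) * K log2 K = log2 K = 2 for K = 4
    assert spec["g"] == pytest.approx(2.0)


def test_specificity_invariant_to_scaling_a_gene():
    base = pd.DataFrame([[1.0, 3.0, 6.0]], index=["g"], columns=list("ABC"))
    w = pd.Series([1.0], index=["g"])
    a = specificity_scores(base, w, K=3)
    b = specificity_scores(base * 17.0, w, K=3)
    assert a["g"] == pytest.approx(b["g"])


@settings(max_examples=60, deadline=None)
@given(hnp.arrays(float, (6, 4), elements=hst.floats(0, 50)))
def test_specificity_bounded_by_weighted_entropy(meanX):
    df = pd.DataFrame(meanX, index=[f"g{i}" for i in range(6)], columns=list("ABCD"))
    w = gene_weights(df) if df.to_numpy().max() > df.max(axis=1).min() else pd.Series(1.0, index=df.index)
    spec = specificity_scores(df, w, K=4)
    assert (spec >= -1e-9).all()
    assert (spec <= w * np.log2(4) + 1e-9).all()


def test_mean_expression_identities():
    mat = ExpressionMatrix(np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 2.0]]),
                           ["g1", "g2"], ["a", "b", "c"], "normalized")
    sc = spotmap.SCReference(
        ExpressionMatrix(np.ones((2, 3)), ["g1", "g2"], ["a", "b", "c"]),
        ["T0", "T0", "T0"], ["T0"])
    meanX = mean_expression_by_type(sc, mat)
    # 3 cells (1, 2, 3) in one type -> mean 2
    assert meanX.loc["g1", "T0"] == pytest.approx(2.0)
    assert meanX.loc["g2", "T0"] == pytest.approx(2.0)


def test_one_cell_per_type_mean_equals_columns():
    vals = np.array([[1.0, 5.0], [2.0, 6.0]])
    mat = ExpressionMatrix(vals, ["g1", "g2"], ["a", "b"], "normalized")
    sc = spotmap.SCReference(
        ExpressionMatrix(vals, ["g1", "g2"], ["a", "b"]), ["T0", "T1"], ["T0", "T1"])
    meanX = mean_expression_by_type(sc, mat)
    np.testing.assert_allclose(meanX.to_numpy(), vals)


def test_planted_markers_recovered_exactly(small_sc):
    sc, planted = small_sc
    table = compute_specificity_table(sc, normalize(sc.matrix))
    ms = select_markers(sc, table, n_top=20)
    for t in sc.type_index:
        assert set(ms.per_type[t]) == set(planted.per_type[t])
        # within-type order is by descending specificity
        specs = table.table.loc[ms.per_type[t], "spec"].to_numpy()
        assert np.all(np.diff(specs) <= 1e-12)


def test_extreme_variance_gene_excluded(small_sc):
    sc, planted = small_sc
    vals = sc.matrix.dense().copy()
    cols = sc.type_columns(sc.type_index[0])
    outlier = 250  # background gene, forced wildly bimodal in type 0
    vals[outlier, cols] = 0.0
    vals[outlier, cols[: len(cols) // 4]] = 400.0
    noisy = sc.with_matrix(ExpressionMatrix(
        vals, sc.matrix.gene_ids, sc.matrix.column_ids, "counts"))
    table = compute_specificity_table(noisy, normalize(noisy.matrix))
    row = table.table.iloc[outlier]
    assert row["assigned_type"] == sc.type_index[0]
    assert not row["variance_pass"]
    ms = select_markers(noisy, table, n_top=300)
    assert noisy.matrix.gene_ids[outlier] not in ms.per_type[sc.type_index[0]]


def test_n_top_larger_than_available_returns_all(small_sc):
    sc, _ = small_sc
    table = compute_specificity_table(sc, normalize(sc.matrix))
    ms = select_markers(sc, table, n_top=10_000)
    assert ms.m <= sc.matrix.n_genes
    assert sum(len(v) for v in ms.per_type.values()) == sc.matrix.n_genes


def test_selection_invariant_to_gene_permutation(small_sc, rng):
    sc, _ = small_sc
    perm = rng.permutation(sc.matrix.n_genes)
    shuffled = sc.with_matrix(ExpressionMatrix(
        sc.matrix.dense()[perm], [sc.matrix.gene_ids[i] for i in perm],
        list(sc.matrix.column_ids), "counts"))
    a = select_markers(sc, compute_specificity_table(sc, normalize(sc.matrix)), n_top=20)
    b = select_markers(shuffled, compute_specificity_table(shuffled, normalize(shuffled.matrix)), n_top=20)
    for t in sc.type_index:
        assert set(a.per_type[t]) == set(b.per_type[t])


def test_marker_union_preserves_first_seen_order():
    ms = spotmap.markers.MarkerSet({"A": ["g1", "g2"], "B": ["g2", "g3"]})
    assert ms.union == ["g1", "g2", "g3"]
    assert ms.m == 3
    assert ms.restrict_to(["g2", "g3"]).per_type["A"] == ["g2"]
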