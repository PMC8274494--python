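"""Variance filtering and Kennard-Stone splitting."""

from __future__ import annotations

import numpy as np
import pytest

from ersar.dataset import (
    DatasetError,
    FeatureMatrix,
    kennard_stone_indices,
    kennard_stone_split,
    variance_filter,
)


def fm(values, ids=None, names=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(ids, names, values)


def ks_oracle(X, k):
    """Exhaustive greedy-maximin reference: recomputes every pairwise
    distance naively at each step; first-index tie-break."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best, bd = None, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(X[i] - X[j]))
            if d > bd + 1e-12:
                bd, best = d, (i, j)
    if k == 1:
        return [best[0]]
    sel = list(best)
    while len(sel) < k:
        bi, bdist = None, -1.0
        for c in range(n):
            if c in sel:
                continue
            dmin = min(float(np.linalg.norm(X[c] - X[s])) for s in sel)
            if dmin > bdist + 1e-12:
                bdist, bi = dmin, c
        sel.append(bi)
    return sel


class TestVarianceFilter:
    def test_constant_column_removed_balanced_retained(self):
        values = np.ones((10, 2))
        values[:5, 1] = 0  # SD 0.527 (ddof=1) -> retained
        filtered, record = variance_filter(fm(values, names=["const", "balanced"]))
        assert filtered.feature_names == ["balanced"]
        assert record.removed_features == ["const"]
        assert record.retained_count == 1

    def test_one_in_200_binary_column_removed(self):
        # sample SD = sqrt(0.995/199) ~ 0.0707 < 0.1
        col = np.zeros((200, 1))
        col[0] = 1
        assert col.std(ddof=1) == pytest.approx(0.0707, abs=1e-4)
        with pytest.raises(DatasetError):
            variance_filter(fm(col))  # the only column is removed -> error

    def test_column_order_preserved(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 2, size=(50, 6)).astype(float)
        values[:, 2] = 1.0
        filtered, _ = variance_filter(fm(values))
        assert filtered.feature_names == ["f0", "f1", "f3", "f4", "f5"]

    def test_all_removed_advises_threshold(self):
        with pytest.raises(DatasetError, match="threshold"):
            variance_filter(fm(np.ones((5, 3))))


class TestKennardStone:
    def test_farthest_pair_on_a_line(self):
        split = kennard_stone_split(fm(np.array([[0.0], [1.0], [10.0]])), fraction=0.6)
        assert set(split.internal_ids) == {"c0", "c2"}
        assert split.external_ids == ["c1"]

    def test_fraction_one_selects_everything(self):
        split = kennard_stone_split(fm(np.random.default_rng(1).random((6, 2))), fraction=1.0)
        assert sorted(split.internal_ids) == [f"c{i}" for i in range(6)]
        assert split.external_ids == []

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(DatasetError):
            kennard_stone_split(fm(np.zeros((4, 2))), fraction=fraction)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n, d = int(rng.integers(2, 13)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, d))
            k = int(rng.integers(1, n + 1))
            assert kennard_stone_indices(X, k) == ks_oracle(X, k)

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        base = kennard_stone_split(fm(X), fraction=0.5)
        perm = rng.permutation(20)
        shuffled = kennard_stone_split(
            FeatureMatrix([f"c{i}" for i in perm], [f"f{j}" for j in range(4)], X[perm]),
            fraction=0.5,
        )
        assert set(base.internal_ids) == set(shuffled.internal_ids)

    def test_maximin_coverage_property(self):
        # every external point sits at least as close to the internal set as
        # the last-selected internal point did when it was added
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        order = kennard_stone_indices(X, 10)
        internal = X[order]
        last_gap = min(np.linalg.norm(internal[-1] - internal[s]) for s in range(9))
        for c in range(15):
            if c in order:
                continue
            gap = min(float(np.linalg.norm(X[c] - p)) for p in internal)
            assert gap <= last_gap + 1e-9

    def test_filter_then_split_matches_composed_pipeline(self):
        rng = np.random.default_rng(11)
        values = rng.integers(0, 2, size=(30, 8)).astype(float)
        values[:, 4] = 0.0
        matrix = fm(values)
        filtered, _ = variance_filter(matrix)
        direct = kennard_stone_split(filtered)
        recomputed = kennard_stone_split(variance_filter(matrix)[0])
        assert direct.internal_ids == recomputed.internal_ids
        assert direct.external_ids == recomputed.external_ids


def test_matrix_csv_round_trip(tmp_path):
    m = fm(np.arange(12).reshape(4, 3))
    p = tmp_path / "m.csv"
    m.to_csv(p)
    back = FeatureMatrix.from_csv(p)
    assert back.ids == m.ids
    assert back.feature_names == m.feature_names
    assert np.allclose(back.values, m.values)
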