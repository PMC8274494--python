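"""Random-forest training core: metrics, tuning, CV, importance ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ersar.dataset import FeatureMatrix
from ersar.model import (
    ConfusionMatrix,
    ModelConfig,
    ModelError,
    cross_validate,
    evaluate_on,
    metrics,
    rank_features,
    tune_and_train,
)

counts = st.integers(min_value=0, max_value=500)


def planted_problem(n=200, n_features=20, seed=0, flip=0):
    """Binary matrix with one perfectly separating bit plus noise bits."""
    rng = np.random.default_rng(seed)
    y = np.array(["active"] * (n // 2) + ["inactive"] * (n - n // 2))
    values = rng.integers(0, 2, size=(n, n_features)).astype(float)
    values[:, 0] = (y == "active").astype(float)
    for i in rng.choice(n, size=flip, replace=False):
        values[i, 0] = 1 - values[i, 0]
    X = FeatureMatrix([f"c{i}" for i in range(n)], [f"f{j}" for j in range(n_features)], values)
    return X, list(y)


class TestMetrics:
    @pytest.mark.parametrize(
        "cm,expect",
        [
            (ConfusionMatrix(50, 50, 0, 0), dict(ac=100, sn=100, sp=100, mcc=1.0)),
            (ConfusionMatrix(0, 0, 50, 50), dict(ac=0, sn=0, sp=0, mcc=-1.0)),
            (ConfusionMatrix(50, 0, 50, 0), dict(ac=50, sn=100, sp=0, mcc=0.0)),
        ],
    )
    def test_closed_forms(self, cm, expect):
        r = metrics(cm)
        assert r.ac == pytest.approx(expect["ac"])
        assert r.sn == pytest.approx(expect["sn"])
        assert r.sp == pytest.approx(expect["sp"])
        assert r.mcc == pytest.approx(expect["mcc"])

    def test_empty_matrix_is_error(self):
        with pytest.raises(ModelError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @given(counts, counts, counts, counts)
    def test_mcc_symmetric_under_class_swap(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        a = metrics(ConfusionMatrix(tp, tn, fp, fn)).mcc
        b = metrics(ConfusionMatrix(tn, tp, fn, fp)).mcc
        assert a == pytest.approx(b)

    @given(counts, counts, counts, counts)
    def test_mcc_bounded(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        assert -1.0 <= metrics(ConfusionMatrix(tp, tn, fp, fn)).mcc <= 1.0

    def test_from_labels_matches_hand_count(self):
        y = ["active", "active", "inactive", "inactive", "active"]
        p = ["active", "inactive", "inactive", "active", "active"]
        cm = ConfusionMatrix.from_labels(y, p)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 1, 1)


class TestCrossValidate:
    def test_pooled_confusion_partitions_data(self):
        X, y = planted_problem(n=60, seed=2, flip=6)
        folds, pooled = cross_validate(50, 3, X, y, k=5, seed=0)
        assert len(folds) == 5
        assert pooled.confusion.total == 60

    def test_fixed_seed_reproducible(self):
        X, y = planted_problem(n=40, seed=3, flip=4)
        _, a = cross_validate(50, 3, X, y, k=4, seed=7)
        _, b = cross_validate(50, 3, X, y, k=4, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_single_class_is_error(self):
        X, _ = planted_problem(n=20)
        with pytest.raises(ModelError):
            cross_validate(50, 3, X, ["active"] * 20, k=5, seed=0)

    def test_too_small_class_is_error(self):
        X, _ = planted_problem(n=20)
        y = ["active"] * 3 + ["inactive"] * 17
        with pytest.raises(ModelError, match="stratify"):
            cross_validate(50, 3, X, y, k=5, seed=0)


class TestTuneAndTrain:
    def test_grid_is_fully_scored(self):
        X, y = planted_problem(n=60, seed=4, flip=6)
        cfg = ModelConfig(ntree_grid=(50, 100), mtry_grid=(2, 4, 6), cv_folds=3, seed=0)
        model = tune_and_train(X, y, cfg)
        assert len(model.tuning_table) == 6
        assert model.chosen_ntree in cfg.ntree_grid
        assert model.chosen_mtry in cfg.mtry_grid

    def test_oversized_mtry_points_skipped_with_warning(self):
        X, y = planted_problem(n=40, n_features=4, seed=5, flip=4)
        cfg = ModelConfig(ntree_grid=(50,), mtry_grid=(2, 30), cv_folds=3, seed=0)
        with pytest.warns(UserWarning, match="mtry"):
            model = tune_and_train(X, y, cfg)
        assert len(model.tuning_table) == 1
        assert model.chosen_mtry == 2

    def test_single_class_labels_rejected(self):
        X, _ = planted_problem(n=20)
        with pytest.raises(ModelError):
            tune_and_train(X, ["active"] * 20, ModelConfig(ntree_grid=(50,), mtry_grid=(2,)))

    @pytest.mark.parametrize("seed", range(10))
    def test_separable_benchmark_recovered_across_seeds(self, seed):
        # planted noise-free signal, n=200: CV MCC should be near-perfect and
        # the planted bit must rank first by Gini importance
        X, y = planted_problem(n=200, seed=seed)
        cfg = ModelConfig(ntree_grid=(100,), mtry_grid=(5,), cv_folds=5, seed=seed)
        model = tune_and_train(X, y, cfg)
        assert model.cv_report.mcc >= 0.9
        assert rank_features(model)[0].feature_name == "f0"

    def test_resubstitution_at_least_cv_accuracy(self):
        X, y = planted_problem(n=100, seed=6, flip=10)
        cfg = ModelConfig(ntree_grid=(100,), mtry_grid=(4,), cv_folds=5, seed=0)
        model = tune_and_train(X, y, cfg)
        assert model.training_report.ac >= model.cv_report.ac - 1.0  # soft sanity margin


class TestRankFeatures:
    def test_constant_feature_has_zero_importance(self):
        X, y = planted_problem(n=60, seed=8, flip=6)
        X.values[:, 3] = 1.0
        model = tune_and_train(X, y, ModelConfig(ntree_grid=(100,), mtry_grid=(4,), cv_folds=3, seed=0))
        ranked = {fi.feature_name: fi.mdgi for fi in rank_features(model)}
        assert ranked["f3"] == 0.0

    def test_output_covers_all_features_with_valid_ranks(self):
        X, y = planted_problem(n=60, seed=9, flip=6)
        model = tune_and_train(X, y, ModelConfig(ntree_grid=(50,), mtry_grid=(4,), cv_folds=3, seed=0))
        ranked = rank_features(model)
        assert len(ranked) == X.n_features
        assert [fi.rank for fi in ranked] == list(range(1, X.n_features + 1))
        mdgis = [fi.mdgi for fi in ranked]
        assert mdgis == sorted(mdgis, reverse=True)
        assert len(rank_features(model, top_k=5)) == 5
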