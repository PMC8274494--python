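"""Random-forest classification core.

Training follows the classical CSAR recipe: a grid over the forest size
(``ntree``, sklearn ``n_estimators``) and the per-split feature draw
(``mtry``, sklearn ``max_features``) is scored by mean stratified 5-fold
cross-validated MCC, the best pair (ties to the smaller ntree, then smaller
mtry) is refit on the full internal set, and models are reported with the
four standard binary-classification figures::

    Ac  = 100 * (TP + TN) / (TP + TN + FP + FN)
    Sn  = 100 * TP / (TP + FN)
    Sp  = 100 * TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with "active" as the positive class and the 0/0 convention MCC = 0.  Feature
importance is the forest's mean decrease of the Gini impurity (MDGI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .curation import ACTIVE, INACTIVE
from .dataset import FeatureMatrix

DEFAULT_NTREE_GRID = tuple(range(100, 1001, 100))
DEFAULT_MTRY_GRID = tuple(range(5, 31, 5))


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID
    cv_folds: int = 5
    tuning_metric: str = "mcc"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ntree_grid or not self.mtry_grid:
            raise ModelError("tuning grids must be non-empty")
        if self.cv_folds < 2:
            raise ModelError("cv_folds must be >= 2")
        if self.tuning_metric not in {"mcc", "ac"}:
            raise ModelError(f"unsupported tuning metric {self.tuning_metric!r}")

    def to_dict(self) -> dict:
        return {
            "ntree_grid": list(self.ntree_grid),
            "mtry_grid": list(self.mtry_grid),
            "cv_folds": self.cv_folds,
            "tuning_metric": self.tuning_metric,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            ntree_grid=tuple(d.get("ntree_grid", DEFAULT_NTREE_GRID)),
            mtry_grid=tuple(d.get("mtry_grid", DEFAULT_MTRY_GRID)),
            cv_folds=int(d.get("cv_folds", 5)),
            tuning_metric=str(d.get("tuning_metric", "mcc")),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ModelError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str],
                    positive: str = ACTIVE) -> "ConfusionMatrix":
        if len(y_true) != len(y_pred):
            raise ModelError("label/prediction length mismatch")
        tp = tn = fp = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == positive:
                tp, fn = (tp + 1, fn) if p == positive else (tp, fn + 1)
            else:
                tn, fp = (tn + 1, fp) if p != positive else (tn, fp + 1)
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass(frozen=True)
class EvaluationReport:
    context: str  # training | training_oob | cv | test
    ac: float
    sn: float
    sp: float
    mcc: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "ac": self.ac,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "confusion": self.confusion.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            context=d["context"], ac=d["ac"], sn=d["sn"], sp=d["sp"], mcc=d["mcc"],
            confusion=ConfusionMatrix(**d["confusion"]),
        )


@dataclass(frozen=True)
class FeatureImportance:
    feature_name: str
    mdgi: float
    rank: int


def metrics(cm: ConfusionMatrix, context: str = "test") -> EvaluationReport:
    """Ac/Sn/Sp (percent) and MCC from a confusion matrix.

    A zero Sn/Sp denominator yields 0; a zero factor in the MCC denominator
    yields MCC = 0 (the standard convention for degenerate margins).
    """
    if cm.total == 0:
        raise ModelError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    ac = 100.0 * (tp + tn) / cm.total
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return EvaluationReport(context=context, ac=ac, sn=sn, sp=sp, mcc=mcc, confusion=cm)


def _as_xy(X: FeatureMatrix | np.ndarray, y: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    y_arr = np.asarray(list(y))
    if values.shape[0] != y_arr.size:
        raise ModelError("X/y length mismatch")
    return values.astype(float), y_arr


def make_forest(ntree: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
        bootstrap=True,
    )


def cross_validate(
    ntree: int,
    mtry: int,
    X: FeatureMatrix | np.ndarray,
    y: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> tuple[list[EvaluationReport], EvaluationReport]:
    """Stratified k-fold CV of one (ntree, mtry) forest.

    Fold assignment is a pure function of the seed.  Returns per-fold reports
    and the pooled report (pooled confusion = sum of fold confusions, so the
    pooled totals partition the data set exactly once).
    """
    values, y_arr = _as_xy(X, y)
    if k < 2:
        raise ModelError("k must be >= 2")
    classes, counts = np.unique(y_arr, return_counts=True)
    if classes.size < 2:
        raise ModelError("need both classes for cross-validation")
    if counts.min() < k:
        raise ModelError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvaluationReport] = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for train_idx, test_idx in skf.split(values, y_arr):
        forest = make_forest(ntree, mtry, seed)
        forest.fit(values[train_idx], y_arr[train_idx])
        pred = forest.predict(values[test_idx])
        cm = ConfusionMatrix.from_labels(y_arr[test_idx], pred)
        fold_reports.append(metrics(cm, context="cv"))
        pooled = pooled + cm
    return fold_reports, metrics(pooled, context="cv")


@dataclass
class TrainedModel:
    target_name: str
    config_used: ModelConfig
    chosen_ntree: int
    chosen_mtry: int
    feature_names: list[str]
    estimator: RandomForestClassifier
    training_report: EvaluationReport
    training_oob_accuracy: float
    cv_report: EvaluationReport
    cv_fold_reports: list[EvaluationReport] = field(default_factory=list)
    tuning_table: list[dict] = field(default_factory=list)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_active_probability(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        active_col = list(self.estimator.classes_).index(ACTIVE)
        return proba[:, active_col]


def tune_and_train(
    X: FeatureMatrix,
    y: Sequence[str],
    config: ModelConfig = ModelConfig(),
    target_name: str = "target",
) -> TrainedModel:
    """Grid-tune (ntree, mtry) by mean CV MCC and refit on the full set.

    Every grid pair is scored by the mean per-fold tuning metric over the
    same seeded stratified folds; grid points with mtry exceeding the feature
    count are skipped with a warning.  Ties resolve to the smaller ntree,
    then the smaller mtry, by scanning the grid in ascending order with a
    strict-improvement rule.  The refit forest also records its out-of-bag
    accuracy (the bagging-native training estimate) alongside the
    resubstitution report.
    """
    values, y_arr = _as_xy(X, y)
    if np.unique(y_arr).size < 2:
        raise ModelError("training labels contain a single class")
    n_features = values.shape[1]
    tuning_table: list[dict] = []
    best: tuple[float, int, int] | None = None
    for ntree in sorted(config.ntree_grid):
        for mtry in sorted(config.mtry_grid):
            if mtry > n_features:
                warnings.warn(
                    f"skipping grid point mtry={mtry} > {n_features} features", stacklevel=2
                )
                continue
            fold_reports, pooled = cross_validate(
                ntree, mtry, values, y_arr, k=config.cv_folds, seed=config.seed
            )
            attr = config.tuning_metric
            score = float(np.mean([getattr(r, attr) for r in fold_reports]))
            tuning_table.append(
                {"ntree": ntree, "mtry": mtry, "mean_cv_" + attr: score,
                 "pooled_cv_mcc": pooled.mcc, "pooled_cv_ac": pooled.ac}
            )
            if best is None or score > best[0]:
                best = (score, ntree, mtry)
    if best is None:
        raise ModelError("every grid point was skipped (mtry grid exceeds feature count)")
    _, ntree, mtry = best

    forest = make_forest(ntree, mtry, config.seed)
    forest.set_params(oob_score=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB of small forests can be sparse
        forest.fit(values, y_arr)
    resub = metrics(ConfusionMatrix.from_labels(y_arr, forest.predict(values)),
                    context="training")
    fold_reports, pooled = cross_validate(ntree, mtry, values, y_arr,
                                          k=config.cv_folds, seed=config.seed)
    return TrainedModel(
        target_name=target_name,
        config_used=config,
        chosen_ntree=ntree,
        chosen_mtry=mtry,
        feature_names=list(X.feature_names),
        estimator=forest,
        training_report=resub,
        training_oob_accuracy=float(forest.oob_score_) * 100.0,
        cv_report=pooled,
        cv_fold_reports=fold_reports,
        tuning_table=tuning_table,
    )


def rank_features(model: TrainedModel, top_k: int | None = None) -> list[FeatureImportance]:
    """Features ordered by non-increasing mean decrease of Gini impurity.

    Ranks are 1..k; ties keep the training column order (stable sort), so the
    ranking is deterministic.  ``top_k`` truncates the list (the conventional
    interpretation plot uses the top 20).
    """
    if not hasattr(model.estimator, "feature_importances_"):
        raise ModelError("model is not fitted")
    mdgi = np.asarray(model.estimator.feature_importances_, dtype=float)
    order = np.argsort(-mdgi, kind="stable")
    ranked = [
        FeatureImportance(feature_name=model.feature_names[j], mdgi=float(mdgi[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]
    return ranked[:top_k] if top_k is not None else ranked


def evaluate_on(model: TrainedModel, X: np.ndarray, y: Sequence[str],
                context: str = "test") -> EvaluationReport:
    pred = model.predict_labels(X)
    return metrics(ConfusionMatrix.from_labels(list(y), list(pred)), context=context)
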