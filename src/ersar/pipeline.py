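"""End-to-end orchestration: dual-target training and batch prediction.

``train_pipeline`` runs, per receptor subtype: standardize -> curate ->
fingerprint -> near-constant filter -> Kennard-Stone 80/20 split -> grid-tuned
random forest (training, 5-fold CV and external-test evaluation) -> PCA
bounding-box applicability domain, and writes a self-contained model artifact
per target.  ``predict`` replays the training-time featurization (same
dictionary, same retained bits, same standardizer rules) from the artifact,
reports per-target labels, active-class probabilities and domain flags, and
derives a subtype-selectivity call from the two labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

from . import chem
from .chem import ActivityRecord, ChemError, Molecule, parse_and_standardize, read_activity_table
from .curation import ACTIVE, INACTIVE, CurationConfig, CuratedDataset, curate
from .dataset import (
    FeatureMatrix,
    FilterRecord,
    SplitResult,
    kennard_stone_split,
    variance_filter,
)
from .dictionaries import builtin_dictionary, canonical_family
from .domain import DomainModel, fit_domain, in_domain_matrix
from .fingerprints import (
    FingerprintDictionary,
    compute_matrix,
    load_dictionary,
    save_dictionary,
)
from .model import (
    EvaluationReport,
    ModelConfig,
    TrainedModel,
    evaluate_on,
    rank_features,
    tune_and_train,
)

SELECTIVITY_CALLS = ("alpha_selective", "beta_selective", "dual_active", "dual_inactive")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun training end to end."""

    fingerprint: str = "substructure"
    mode: str = "presence"  # presence | count
    sd_threshold: float = 0.1
    split_fraction: float = 0.8
    ad_components: int = 2
    activity_type: str = "IC50"
    top_k_features: int = 20
    curation: CurationConfig = field(default_factory=CurationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        canonical_family(self.fingerprint)  # raises early on unknown family
        if self.mode not in {"presence", "count"}:
            raise PipelineError(f"unknown fingerprint mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "fingerprint": self.fingerprint,
            "mode": self.mode,
            "sd_threshold": self.sd_threshold,
            "split_fraction": self.split_fraction,
            "ad_components": self.ad_components,
            "activity_type": self.activity_type,
            "top_k_features": self.top_k_features,
            "curation": {
                "active_threshold_pic50": self.curation.active_threshold_pic50,
                "inactive_threshold_pic50": self.curation.inactive_threshold_pic50,
                "duplicate_rule": self.curation.duplicate_rule,
            },
            "model": self.model.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cur = d.pop("curation", {})
        mod = d.pop("model", {})
        return cls(
            curation=CurationConfig(**cur) if cur else CurationConfig(),
            model=ModelConfig.from_dict(mod) if mod else ModelConfig(),
            **d,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise PipelineError(f"{path}: config must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise PipelineError(f"{path}: bad config: {exc}") from exc


@dataclass
class TargetResult:
    """Everything produced for one receptor subtype."""

    target_name: str
    curated: CuratedDataset
    molecules: list[Molecule]
    matrix: FeatureMatrix  # filtered
    filter_record: FilterRecord
    split: SplitResult
    model: TrainedModel
    test_report: EvaluationReport
    domain: DomainModel
    importances: list  # top-k FeatureImportance
    artifact_dir: Path | None = None

    def report_dict(self) -> dict:
        return {
            "target": self.target_name,
            "curation": self.curated.summary(),
            "n_features_retained": self.filter_record.retained_count,
            "n_internal": len(self.split.internal_ids),
            "n_external": len(self.split.external_ids),
            "chosen_ntree": self.model.chosen_ntree,
            "chosen_mtry": self.model.chosen_mtry,
            "evaluation": {
                "training": self.model.training_report.to_dict(),
                "cv": self.model.cv_report.to_dict(),
                "test": self.test_report.to_dict(),
            },
            "training_oob_accuracy": self.model.training_oob_accuracy,
            "top_features": [
                {"feature": fi.feature_name, "mdgi": fi.mdgi, "rank": fi.rank}
                for fi in self.importances
            ],
        }


def _resolve_dictionary(config: PipelineConfig) -> FingerprintDictionary:
    return builtin_dictionary(config.fingerprint)


def standardize_records(records: Sequence[ActivityRecord]) -> list[Molecule]:
    mols = []
    for rec in records:
        mols.append(parse_and_standardize(rec.smiles, mol_id=rec.compound_id))
    return mols


def train_target(
    records: Sequence[ActivityRecord],
    config: PipelineConfig,
    target_name: str,
    seed: int | None = None,
) -> TargetResult:
    """Run the full single-target training pipeline on raw activity records."""
    model_config = config.model if seed is None else ModelConfig.from_dict(
        {**config.model.to_dict(), "seed": seed}
    )
    curated = curate(records, config.curation, activity_type=config.activity_type)
    if curated.n_active == 0 or curated.n_inactive == 0:
        raise PipelineError(
            f"{target_name}: curation left a single class "
            f"({curated.n_active} active / {curated.n_inactive} inactive)"
        )
    mols = standardize_records(curated.records)
    dictionary = _resolve_dictionary(config)
    raw_matrix = compute_matrix(mols, dictionary, config.mode)
    matrix, filter_record = variance_filter(raw_matrix, config.sd_threshold)
    split = kennard_stone_split(matrix, config.split_fraction)
    if not split.external_ids:
        raise PipelineError(f"{target_name}: split left no external compounds")

    labels = {rec.compound_id: rec.label for rec in curated.records}
    X_int = matrix.subset_rows(split.internal_ids)
    X_ext = matrix.subset_rows(split.external_ids)
    y_int = [labels[cid] for cid in split.internal_ids]
    y_ext = [labels[cid] for cid in split.external_ids]
    if len(set(y_int)) < 2:
        raise PipelineError(f"{target_name}: internal set has a single class")

    model = tune_and_train(X_int, y_int, model_config, target_name=target_name)
    test_report = evaluate_on(model, X_ext.values, y_ext, context="test")
    domain = fit_domain(X_int, n_components=config.ad_components)
    importances = rank_features(model, top_k=config.top_k_features)
    return TargetResult(
        target_name=target_name,
        curated=curated,
        molecules=mols,
        matrix=matrix,
        filter_record=filter_record,
        split=split,
        model=model,
        test_report=test_report,
        domain=domain,
        importances=importances,
    )


# ---------------------------------------------------------------------------
# model artifact (directory bundle)
# ---------------------------------------------------------------------------

def save_artifact(result: TargetResult, config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write a self-contained model bundle.

    Contents: the serialized forest, the fingerprint dictionary as TSV, and a
    JSON metadata file carrying the retained feature list, filter record,
    configuration, standardizer rule set, evaluation reports and the domain
    model — everything needed to featurize queries identically at predict
    time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    joblib.dump(result.model.estimator, out / "forest.joblib")
    save_dictionary(_resolve_dictionary(config), out / "dictionary.tsv")
    meta = {
        "target_name": result.target_name,
        "pipeline_config": config.to_dict(),
        "model_config": result.model.config_used.to_dict(),
        "tautomer_ruleset": chem.TAUTOMER_RULESET,
        "chosen_ntree": result.model.chosen_ntree,
        "chosen_mtry": result.model.chosen_mtry,
        "feature_names": result.model.feature_names,
        "filter_record": result.filter_record.to_dict(),
        "split": {
            "internal_ids": result.split.internal_ids,
            "external_ids": result.split.external_ids,
            "fraction": result.split.fraction,
            "distance_metric": result.split.distance_metric,
        },
        "reports": {
            "training": result.model.training_report.to_dict(),
            "training_oob_accuracy": result.model.training_oob_accuracy,
            "cv": result.model.cv_report.to_dict(),
            "test": result.test_report.to_dict(),
        },
        "domain": result.domain.to_dict(),
        "top_features": [
            {"feature": fi.feature_name, "mdgi": fi.mdgi, "rank": fi.rank}
            for fi in result.importances
        ],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    result.artifact_dir = out
    return out


@dataclass
class LoadedArtifact:
    target_name: str
    estimator: object
    dictionary: FingerprintDictionary
    mode: str
    feature_names: list[str]
    domain: DomainModel
    meta: dict

    def featurize(self, mols: Sequence[Molecule]) -> np.ndarray:
        full = compute_matrix(mols, self.dictionary, self.mode)
        return full.subset_columns(self.feature_names).values.astype(float)


def load_artifact(artifact_dir: str | Path) -> LoadedArtifact:
    out = Path(artifact_dir)
    meta = json.loads((out / "meta.json").read_text())
    config = PipelineConfig.from_dict(meta["pipeline_config"])
    dictionary = load_dictionary(out / "dictionary.tsv",
                                 name=canonical_family(config.fingerprint))
    return LoadedArtifact(
        target_name=meta["target_name"],
        estimator=joblib.load(out / "forest.joblib"),
        dictionary=dictionary,
        mode=config.mode,
        feature_names=list(meta["feature_names"]),
        domain=DomainModel.from_dict(meta["domain"]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# dual-target training and prediction
# ---------------------------------------------------------------------------

def train_pipeline(
    alpha_table: str | Path,
    beta_table: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Train both subtype models from activity tables; returns the report.

    With ``out_dir`` set, writes ``alpha/`` and ``beta/`` artifacts plus a
    consolidated ``report.json``.
    """
    results = {}
    for name, path in (("alpha", alpha_table), ("beta", beta_table)):
        table = read_activity_table(path)
        results[name] = train_target(table.records, config, target_name=f"ER{name}", seed=seed)
        results[name].read_report = {"n_rows": table.n_rows, "n_dropped": table.n_dropped}
    report = {
        "config": config.to_dict(),
        "targets": {name: res.report_dict() for name, res in results.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            save_artifact(res, config, out / name)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    report["_results"] = results  # in-memory handles for library callers
    return report


def selectivity_call(alpha_label: str, beta_label: str) -> str:
    """Pure function of the two predicted labels."""
    a, b = alpha_label == ACTIVE, beta_label == ACTIVE
    if a and b:
        return "dual_active"
    if a:
        return "alpha_selective"
    if b:
        return "beta_selective"
    return "dual_inactive"


def predict(
    smiles_pairs: Sequence[tuple[str, str]],
    alpha_artifact: str | Path | LoadedArtifact,
    beta_artifact: str | Path | LoadedArtifact,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Batch-predict both subtypes for (smiles, id) pairs.

    Unparseable rows are reported with an ``error`` column and skipped for
    prediction; the rest proceed.  Columns: compound_id, smiles, pred_ERa,
    prob_ERa, in_AD_ERa, pred_ERb, prob_ERb, in_AD_ERb, selectivity_call.
    """
    alpha = alpha_artifact if isinstance(alpha_artifact, LoadedArtifact) else load_artifact(alpha_artifact)
    beta = beta_artifact if isinstance(beta_artifact, LoadedArtifact) else load_artifact(beta_artifact)
    rows: list[dict] = []
    ok_mols: list[Molecule] = []
    ok_rows: list[int] = []
    for smiles, cid in smiles_pairs:
        try:
            mol = parse_and_standardize(smiles, mol_id=cid)
        except ChemError as exc:
            rows.append({"compound_id": cid, "smiles": smiles, "error": str(exc)})
            continue
        rows.append({"compound_id": cid, "smiles": mol.smiles_canonical, "error": ""})
        ok_rows.append(len(rows) - 1)
        ok_mols.append(mol)
    if ok_mols:
        for tag, artifact in (("ERa", alpha), ("ERb", beta)):
            X = artifact.featurize(ok_mols)
            labels = artifact.estimator.predict(X)
            proba = artifact.estimator.predict_proba(X)
            active_col = list(artifact.estimator.classes_).index(ACTIVE)
            inside, _ = in_domain_matrix(artifact.domain, X)
            for i, row_idx in enumerate(ok_rows):
                rows[row_idx][f"pred_{tag}"] = labels[i]
                rows[row_idx][f"prob_{tag}"] = float(proba[i, active_col])
                rows[row_idx][f"in_AD_{tag}"] = bool(inside[i])
        for row_idx in ok_rows:
            rows[row_idx]["selectivity_call"] = selectivity_call(
                rows[row_idx]["pred_ERa"], rows[row_idx]["pred_ERb"]
            )
    columns = ["compound_id", "smiles", "pred_ERa", "prob_ERa", "in_AD_ERa",
               "pred_ERb", "prob_ERb", "in_AD_ERb", "selectivity_call", "error"]
    df = pd.DataFrame(rows).reindex(columns=columns)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
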