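"""Feature-matrix container, near-constant filtering, Kennard–Stone splitting.

The Kennard–Stone algorithm is the rational (deterministic, space-covering)
alternative to random train/test splitting: it seeds the training ("internal")
set with the two most distant compounds in descriptor space and then greedily
adds the compound farthest from everything already selected (maximin), so the
internal set spans the occupied descriptor space and the held-out "external"
set falls inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


class DatasetError(ValueError):
    """Raised for unusable matrices or split parameters."""


@dataclass
class FeatureMatrix:
    """Compounds x features grid with provenance of how it was built."""

    ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != (len(self.ids), len(self.feature_names)):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.ids)) != len(self.ids):
            raise DatasetError("duplicate compound ids in feature matrix")

    @property
    def n_compounds(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="compound_id"),
                            columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: dict | None = None) -> "FeatureMatrix":
        return cls(
            ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(),
            provenance=dict(provenance or {}),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {cid: i for i, cid in enumerate(self.ids)}
        rows = [index[cid] for cid in ids]
        return FeatureMatrix(list(ids), list(self.feature_names), self.values[rows],
                             dict(self.provenance))

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        index = {name: j for j, name in enumerate(self.feature_names)}
        cols = [index[name] for name in names]
        return FeatureMatrix(list(self.ids), list(names), self.values[:, cols],
                             dict(self.provenance))


@dataclass
class FilterRecord:
    sd_threshold: float
    removed_features: list[str]
    retained_count: int

    def to_dict(self) -> dict:
        return {
            "sd_threshold": self.sd_threshold,
            "removed_features": list(self.removed_features),
            "retained_count": self.retained_count,
            # filter is fitted on the full dataset before splitting; a known,
            # deliberate information-flow choice mirroring the workflow order
            "fitted_on": "full_dataset_before_split",
        }


@dataclass
class SplitResult:
    internal_ids: list[str]
    external_ids: list[str]
    fraction: float
    distance_metric: str = "euclidean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": list(self.internal_ids) + list(self.external_ids),
                "partition": ["internal"] * len(self.internal_ids)
                + ["external"] * len(self.external_ids),
            }
        )


def variance_filter(matrix: FeatureMatrix, sd_threshold: float = 0.1) -> tuple[FeatureMatrix, FilterRecord]:
    """Drop constant and near-constant features (sample SD below threshold).

    SD uses the n-1 (sample) denominator.  Surviving column order is
    preserved.  Raises if every feature would be removed.
    """
    if matrix.n_compounds < 2:
        raise DatasetError("variance filter needs at least 2 rows")
    sds = matrix.values.astype(float).std(axis=0, ddof=1)
    keep = sds >= sd_threshold
    if not keep.any():
        raise DatasetError(
            f"variance filter with sd_threshold={sd_threshold} removed every feature; "
            "review the threshold or the descriptor set"
        )
    kept_names = [n for n, k in zip(matrix.feature_names, keep) if k]
    removed = [n for n, k in zip(matrix.feature_names, keep) if not k]
    filtered = FeatureMatrix(
        ids=list(matrix.ids),
        feature_names=kept_names,
        values=matrix.values[:, keep],
        provenance=dict(matrix.provenance),
    )
    record = FilterRecord(sd_threshold=sd_threshold, removed_features=removed,
                          retained_count=len(kept_names))
    filtered.provenance["filter"] = record.to_dict()
    return filtered, record


def kennard_stone_indices(X: np.ndarray, n_select: int) -> list[int]:
    """Kennard–Stone selection order on a raw coordinate array.

    Deterministic: seeds with the globally most distant pair (ties resolved to
    the lexicographically smallest index pair), then repeatedly adds the
    unselected point with the largest minimum Euclidean distance to the
    selected set (ties resolved to the lowest row index).  With
    ``n_select == 1`` the lower-index member of the farthest pair is returned.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise DatasetError("Kennard-Stone needs at least 2 points")
    if not 1 <= n_select <= n:
        raise DatasetError(f"cannot select {n_select} of {n} points")
    D = squareform(pdist(X, metric="euclidean"))
    # argmax of the upper triangle; np.argmax returns the first (row-major =
    # lexicographically smallest) maximizing entry
    iu = np.triu_indices(n, k=1)
    flat_best = int(np.argmax(D[iu]))
    i, j = int(iu[0][flat_best]), int(iu[1][flat_best])
    if n_select == 1:
        return [i]
    selected = [i, j]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i, j]] = True
    min_dist = np.minimum(D[i], D[j])
    while len(selected) < n_select:
        min_dist_masked = np.where(in_set, -np.inf, min_dist)
        nxt = int(np.argmax(min_dist_masked))
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def kennard_stone_split(matrix: FeatureMatrix, fraction: float = 0.8) -> SplitResult:
    """Split compounds into internal/external sets by Kennard–Stone.

    The internal set receives ``ceil(fraction * n)`` compounds in selection
    order; the remainder (original row order) is external.  The split is a
    pure function of the ordered matrix — no random state.
    """
    if not (0.0 < fraction <= 1.0):
        raise DatasetError(f"fraction must be in (0, 1], got {fraction}")
    n = matrix.n_compounds
    if n < 2:
        raise DatasetError("need at least 2 compounds to split")
    n_internal = math.ceil(fraction * n)
    order = kennard_stone_indices(matrix.values, n_internal)
    chosen = set(order)
    internal = [matrix.ids[i] for i in order]
    external = [cid for i, cid in enumerate(matrix.ids) if i not in chosen]
    return SplitResult(internal_ids=internal, external_ids=external, fraction=fraction)
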