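"""PCA bounding-box applicability domain.

The domain is fit on the internal (training) set only: descriptors are
mean-centered (no unit-variance scaling — the binary fingerprint bits already
share a scale), projected onto the leading principal components, and the
per-component [min, max] intervals of the internal scores define a closed
axis-aligned box in score space.  A query compound is in-domain iff every one
of its retained component scores falls inside the corresponding closed
interval; by construction 100% of the internal set is in-domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .dataset import FeatureMatrix


class DomainError(ValueError):
    pass


@dataclass
class DomainModel:
    n_components: int
    component_loadings: np.ndarray  # (n_components, n_features)
    center: np.ndarray  # (n_features,)
    box_lo: np.ndarray  # (n_components,)
    box_hi: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_names: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.center.size:
            raise DomainError(
                f"expected {self.center.size} features, got {X.shape[1]}"
            )
        return (X - self.center) @ self.component_loadings.T

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "component_loadings": self.component_loadings.tolist(),
            "center": self.center.tolist(),
            "box_lo": self.box_lo.tolist(),
            "box_hi": self.box_hi.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainModel":
        return cls(
            n_components=int(d["n_components"]),
            component_loadings=np.asarray(d["component_loadings"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            box_lo=np.asarray(d["box_lo"], dtype=float),
            box_hi=np.asarray(d["box_hi"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            feature_names=list(d["feature_names"]),
        )


def fit_domain(X_internal: FeatureMatrix | np.ndarray, n_components: int = 2) -> DomainModel:
    """Fit the bounding box on the internal set.

    Raises for degenerate input (all rows identical — no directions of
    variation to bound) and for ``n_components`` above the feature count or
    the matrix rank.
    """
    feature_names = (
        list(X_internal.feature_names) if isinstance(X_internal, FeatureMatrix) else []
    )
    values = X_internal.values if isinstance(X_internal, FeatureMatrix) else np.asarray(X_internal)
    values = values.astype(float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise DomainError("need at least 2 internal compounds")
    if n_components < 1 or n_components > values.shape[1]:
        raise DomainError(
            f"n_components must be in 1..{values.shape[1]}, got {n_components}"
        )
    if np.allclose(values.var(axis=0), 0.0):
        raise DomainError("internal set is degenerate (all rows identical)")
    rank = np.linalg.matrix_rank(values - values.mean(axis=0))
    if n_components > rank:
        raise DomainError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(values)
    model = DomainModel(
        n_components=n_components,
        component_loadings=np.asarray(pca.components_, dtype=float),
        center=np.asarray(pca.mean_, dtype=float),
        box_lo=np.zeros(n_components),
        box_hi=np.zeros(n_components),
        explained_variance_ratio=np.asarray(pca.explained_variance_ratio_, dtype=float),
        feature_names=feature_names,
    )
    scores = model.transform(values)  # same code path as queries -> exact containment
    model.box_lo = scores.min(axis=0)
    model.box_hi = scores.max(axis=0)
    return model


def in_domain(model: DomainModel, x: np.ndarray) -> tuple[bool, np.ndarray]:
    """Membership flag plus the per-component scores for one compound.

    The box is closed: a score exactly on a boundary is inside.
    """
    scores = model.transform(np.asarray(x, dtype=float).reshape(1, -1))[0]
    inside = bool(np.all(scores >= model.box_lo) and np.all(scores <= model.box_hi))
    return inside, scores


def in_domain_matrix(model: DomainModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized membership over rows of X."""
    scores = model.transform(X)
    inside = np.all((scores >= model.box_lo) & (scores <= model.box_hi), axis=1)
    return inside, scores
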