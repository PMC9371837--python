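"""Serial feature fusion and PCA reduction.

Serial (serial-based extended) fusion concatenates two feature blocks over
the same samples column-wise, so two selected subsets of widths Y and Z fuse
into a single matrix of width K = Y + Z.  The fused matrix is then projected
onto its top-k principal components, keeping only the high-variance
directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import FeatureMatrix


@dataclass
class FusedFeatures(FeatureMatrix):
    """Column-wise concatenation [A | B]; provenance records the block split."""

    provenance: tuple = ()

    @property
    def split(self) -> int:
        return self.provenance[0][1] if self.provenance else self.d


def serial_fuse(a: FeatureMatrix, b: FeatureMatrix,
                a_id: str = "a", b_id: str = "b") -> FusedFeatures:
    """Fuse two aligned feature matrices into one of width ``a.d + b.d``.

    Rows must correspond to the same samples: identical row counts and
    identical label vectors, element-wise and in order.  Feature ids are
    prefixed with the source id to stay unique.
    """
    if a.n != b.n:
        raise ValueError(f"row-count mismatch: {a.n} vs {b.n}")
    if not np.array_equal(a.y, b.y):
        raise ValueError("label vectors differ; sample alignment violated")
    X = np.hstack([a.X, b.X]) if a.d and b.d else np.hstack(
        [a.X.reshape(a.n, a.d), b.X.reshape(b.n, b.d)])
    ids = [f"{a_id}:{f}" for f in a.feature_ids] + \
          [f"{b_id}:{f}" for f in b.feature_ids]
    return FusedFeatures(X=X, y=a.y.copy(), feature_ids=ids,
                         provenance=((a_id, a.d), (b_id, b.d)))


@dataclass
class PCAModel:
    """Mean vector plus top-k orthonormal variance directions.

    ``components`` has shape (k, K) with orthonormal rows;
    ``explained_variance`` is the non-increasing sequence of component
    variances.  Component signs are fixed so each row's largest-magnitude
    loading is positive, making the fit deterministic.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("components are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def input_dim(self) -> int:
        return self.components.shape[1]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "k": self.k,
        }))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        obj = json.loads(Path(path).read_text())
        return cls(mean=np.array(obj["mean"]),
                   components=np.array(obj["components"]),
                   explained_variance=np.array(obj["explained_variance"]))


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit the top-k principal components of the mean-centered rows of X.

    Computed by thin SVD of the centered matrix; variances use the unbiased
    (N-1) normalization.  Requires ``1 <= k <= min(N-1, K)``.
    """
    X = np.asarray(X, dtype=float)
    n, width = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= k <= min(n - 1, width):
        raise ValueError(f"k={k} out of range [1, {min(n - 1, width)}]")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    components = vt[:k]
    # deterministic sign: largest-|loading| coordinate of each row positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    explained = (s[:k] ** 2) / (n - 1)
    return PCAModel(mean=mean, components=components,
                    explained_variance=explained)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the model's components: ``(X - mean) @ Vᵀ``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns; model expects "
                         f"{model.input_dim}")
    return (X - model.mean) @ model.components.T


def pca_inverse_transform(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map scores back to the input space: ``Z @ V + mean``."""
    return np.atleast_2d(Z) @ model.components + model.mean


def reduce_features(fm: FeatureMatrix, k: int) -> tuple[FeatureMatrix, PCAModel]:
    """Fit PCA on ``fm`` and return the reduced matrix plus the model."""
    model = pca_fit(fm.X, k)
    Z = pca_transform(model, fm.X)
    return FeatureMatrix(X=Z, y=fm.y.copy(),
                         feature_ids=[f"pc{i + 1}" for i in range(k)]), model
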