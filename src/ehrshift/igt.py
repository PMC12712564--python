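"""Information-geometric temporal (IGT) projection of yearly batches.

Each temporal batch is represented by an estimated probability distribution;
the square root of the Jensen–Shannon divergence (base 2) between every pair
of batches — a bounded metric in [0, 1] — fills a dissimilarity matrix, and
classical (Torgerson) multidimensional scaling embeds the batches as points in
2 or 3 dimensions. Distances in the embedding approximate the distributional
dissimilarities, so trends, abrupt changes, and temporal subgroups become
visible as geometry. The same machinery embeds interyear model-performance
matrices after converting them to dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .dth import TemporalDistribution
from .errors import DimensionError, NormalizationError, RangeError
from .latent import DensityMap

__all__ = [
    "DissimilarityMatrix",
    "IGTProjection",
    "js_dissimilarity",
    "mds_embed",
    "performance_dissimilarity",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal matrix of batch dissimilarities."""

    labels: list[int]
    values: np.ndarray
    metric: str = "jensen-shannon"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("dissimilarities must be nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path: Path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class IGTProjection:
    """Per-batch coordinates from classical MDS of a dissimilarity matrix."""

    labels: list[int]
    coords: np.ndarray  # (n_batches, k)
    eigenvalues: np.ndarray
    negative_mass: float  # |sum of truncated negative eigenvalues| / sum |eig|

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"dim{k+1}" for k in range(self.coords.shape[1])],
        )

    def write(self, path: Path) -> None:
        self.to_frame().to_csv(path, index_label="year")


def _year_columns(dist) -> tuple[list[int], np.ndarray]:
    if isinstance(dist, TemporalDistribution):
        return list(dist.years), dist.column_matrix()
    if isinstance(dist, DensityMap):
        return list(dist.years), dist.mass
    arr = np.asarray(dist, dtype=float)
    return list(range(arr.shape[1])), arr


def js_dissimilarity(dist, tol: float = 1e-6) -> DissimilarityMatrix:
    """Pairwise sqrt Jensen–Shannon divergence (base 2) between year columns.

    Accepts a :class:`TemporalDistribution`, a :class:`DensityMap`, or a raw
    value × year matrix whose columns are probability vectors. Entries lie in
    [0, 1]; 0·log 0 contributes zero.
    """
    labels, cols = _year_columns(dist)
    sums = cols.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=tol):
        raise NormalizationError(f"year columns must sum to 1, got {sums}")
    n = cols.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = min(jensenshannon(cols[:, i], cols[:, j], base=2), 1.0)
    np.nan_to_num(d, copy=False)  # identical columns can yield tiny negatives/NaN
    return DissimilarityMatrix(labels=labels, values=d)


def mds_embed(dmatrix: DissimilarityMatrix, k: int = 3) -> IGTProjection:
    """Classical (Torgerson) multidimensional scaling to ``k`` dimensions.

    Double-centers the squared dissimilarities, eigendecomposes, and keeps the
    top-``k`` axes ordered by eigenvalue. Negative eigenvalues (non-Euclidean
    part) are truncated at zero and their relative mass reported. Axis signs
    are fixed so the first batch has nonnegative coordinates.
    """
    d = dmatrix.values
    n = d.shape[0]
    if k >= n:
        raise DimensionError(f"k={k} must be smaller than batch count {n}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    negative_mass = float(
        np.abs(eigval[eigval < 0]).sum() / max(np.abs(eigval).sum(), 1e-300)
    )
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)[None, :]
    for axis in range(k):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] *= -1.0
    return IGTProjection(
        labels=list(dmatrix.labels), coords=coords,
        eigenvalues=eigval, negative_mass=negative_mass,
    )


def performance_dissimilarity(
    matrix: pd.DataFrame | np.ndarray,
    labels: list[int] | None = None,
    mode: str = "average",
) -> DissimilarityMatrix:
    """Dissimilarity between years implied by an interyear evaluation matrix.

    ``mode="average"`` (default): D[i, j] = 1 − (M[i, j] + M[j, i]) / 2 — two
    years are similar when models transfer well between them in both
    directions. ``mode="profile"``: mean Manhattan distance between the
    concatenated row+column performance profiles of the two years. Metric
    values must be normalized to [0, 1].
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [int(c) for c in matrix.columns] if labels is None else labels
        m = matrix.to_numpy(dtype=float)
    else:
        m = np.asarray(matrix, dtype=float)
        labels = list(range(m.shape[0])) if labels is None else labels
    finite = m[np.isfinite(m)]
    if (finite < 0).any() or (finite > 1).any():
        raise RangeError("metric values must lie in [0, 1]")
    n = m.shape[0]
    if mode == "average":
        d = 1.0 - (m + m.T) / 2.0
        np.fill_diagonal(d, 0.0)
    elif mode == "profile":
        profiles = np.hstack([m, m.T])  # row then column profile per year
        d = np.abs(profiles[:, None, :] - profiles[None, :, :]).mean(axis=2)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DissimilarityMatrix(labels=labels, values=d, metric=f"performance-{mode}")
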