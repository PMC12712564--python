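"""Linking data-shift structure to model-performance structure.

Years are partitioned twice — once by clustering the data IGT projection,
once by clustering the embedding of each interyear performance matrix — and
the two partitions are cross-tabulated and tested for association with the
two-sided Fisher exact test, followed by Benjamini–Hochberg FDR adjustment
across metrics. A significant association means the unsupervised data-shift
characterization anticipated where model performance changes.

Clustering follows the study design: complete-linkage agglomerative
clustering on Manhattan distances, k-means initialized at the first and last
years' coordinates, and the elbow rule as an advisory choice of k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, ConfigurationError, DegenerateInputError, RangeError
from .igt import IGTProjection, mds_embed, performance_dissimilarity
from .models import EvalMatrix

__all__ = [
    "Partition",
    "ContingencyTable",
    "AssociationResult",
    "hierarchical_partition",
    "kmeans_partition",
    "elbow_k",
    "cross_tab",
    "fisher_exact",
    "fdr_adjust",
    "associate",
]


@dataclass
class Partition:
    """Assignment of each year to one of k clusters."""

    labels: dict[int, int]  # year -> cluster id (0-based)
    method: str
    k: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        found = set(self.labels.values())
        if len(found) != self.k:
            raise ValueError(
                f"partition spans {len(found)} nonempty clusters, expected k={self.k}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": {str(y): int(c) for y, c in self.labels.items()},
                "method": self.method,
                "k": self.k,
                "metadata": self.metadata,
            },
            indent=2,
        )


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_partition: str
    col_partition: str

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = c


@dataclass
class AssociationResult:
    metric: str
    method: str
    p_raw: float
    p_adjusted: float
    table: ContingencyTable

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1 or not 0 <= self.p_adjusted <= 1:
            raise ValueError("p-values must lie in [0, 1]")


def hierarchical_partition(embedding: IGTProjection, k: int = 2) -> Partition:
    """Complete-linkage clustering on Manhattan distances, cut at k clusters."""
    n = len(embedding.labels)
    if k <= 1:
        raise ConfigurationError("k must be at least 2")
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than batch count {n}")
    z = linkage(embedding.coords, method="complete", metric="cityblock")
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(set(raw)) < k:  # all-identical points: force a deterministic cut
        raw = np.array([0] * (n - k + 1) + list(range(1, k)))
    labels = _canonical_labels(embedding.labels, raw)
    return Partition(
        labels=labels, method="hierarchical", k=k,
        metadata={"linkage": "complete", "metric": "cityblock"},
    )


def _canonical_labels(years: list[int], raw: np.ndarray) -> dict[int, int]:
    """Relabel clusters 0..k-1 in order of first appearance along the years."""
    mapping: dict[int, int] = {}
    out: dict[int, int] = {}
    for year, r in zip(years, raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[int(year)] = mapping[r]
    return out


def kmeans_partition(embedding: IGTProjection, k: int = 2) -> Partition:
    """Lloyd's k-means seeded at the first and last years' coordinates.

    Deterministic given the embedding: no random restarts. Runs until the
    centroid shift falls below 1e-9 or 100 iterations.
    """
    if k != 2:
        raise ConfigurationError("k-means partition is defined for k=2")
    x = embedding.coords
    first, last = x[0], x[-1]
    if np.allclose(first, last):
        raise DegenerateInputError("first and last year coordinates coincide")
    centroids = np.stack([first, last]).astype(float)
    assign = np.zeros(len(x), dtype=int)
    for _ in range(100):
        dist = np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2)
        assign = dist.argmin(axis=1)
        new = np.stack(
            [
                x[assign == c].mean(axis=0) if (assign == c).any() else centroids[c]
                for c in range(k)
            ]
        )
        if np.linalg.norm(new - centroids) < 1e-9:
            centroids = new
            break
        centroids = new
    labels = _canonical_labels(embedding.labels, assign)
    return Partition(
        labels=labels, method="kmeans", k=k,
        metadata={"init": "first/last year", "iterations_cap": 100},
    )


def elbow_k(embedding: IGTProjection, k_max: int) -> tuple[int, pd.DataFrame]:
    """Advisory number of clusters from the within-dispersion elbow.

    For k = 1..k_max the years are cut by complete-linkage/Manhattan
    clustering and the total Manhattan dispersion around each cluster's
    coordinate-wise median is summed. The suggested k maximizes the second
    difference of this (non-increasing) curve.
    """
    n = len(embedding.labels)
    if k_max < 3:
        raise ConfigurationError("k_max must be at least 3")
    if k_max >= n:
        raise ConfigurationError("k_max must be smaller than batch count")
    x = embedding.coords
    z = linkage(x, method="complete", metric="cityblock")
    dispersion = []
    for k in range(1, k_max + 1):
        raw = fcluster(z, t=k, criterion="maxclust") if k > 1 else np.ones(n, int)
        total = 0.0
        for c in np.unique(raw):
            pts = x[raw == c]
            total += np.abs(pts - np.median(pts, axis=0)).sum()
        dispersion.append(total)
    curve = pd.DataFrame({"k": range(1, k_max + 1), "dispersion": dispersion})
    d = np.asarray(dispersion)
    second = d[:-2] - 2 * d[1:-1] + d[2:]  # indexed at k = 2..k_max-1
    suggested = int(np.argmax(second)) + 2
    return suggested, curve


def cross_tab(a: Partition, b: Partition) -> ContingencyTable:
    """Count years falling in each (cluster-of-a, cluster-of-b) cell."""
    if set(a.labels) != set(b.labels):
        raise AlignmentError("partitions cover different year sets")
    counts = np.zeros((a.k, b.k), dtype=int)
    for year in a.labels:
        counts[a.labels[year], b.labels[year]] += 1
    return ContingencyTable(counts=counts, row_partition=a.method, col_partition=b.method)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2×2 table (probability-ordering rule).

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's.
    Tables larger than 2×2 are rejected rather than approximated. A zero
    margin makes the table degenerate and returns p = 1 with a warning.
    """
    c = table.counts
    if c.shape != (2, 2):
        raise ConfigurationError(
            "exact test supported for 2x2 tables only; re-cluster with k=2"
        )
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate contingency table (zero margin); p = 1")
        return 1.0
    return float(_scipy_fisher(c, alternative="two-sided")[1])


def fdr_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise RangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def associate(
    data_partition: Partition,
    eval_matrices: dict[str, EvalMatrix],
    method: str = "hierarchical",
    k: int = 2,
    embed_dims: int = 3,
    dissimilarity_mode: str = "average",
) -> list[AssociationResult]:
    """Test each metric's temporal partition against the data partition.

    For every interyear evaluation matrix: convert it to a dissimilarity,
    embed with classical MDS (3 dimensions), partition the years with the
    requested clustering method (k = 2), cross-tabulate against the data-shift
    partition, and apply the Fisher exact test; finally adjust the p-values
    across metrics with Benjamini–Hochberg.
    """
    partition_fn = {
        "hierarchical": hierarchical_partition,
        "kmeans": kmeans_partition,
    }.get(method)
    if partition_fn is None:
        raise ConfigurationError(f"unknown clustering method {method!r}")

    results: list[tuple[str, float, ContingencyTable]] = []
    for metric, em in eval_matrices.items():
        try:
            d = performance_dissimilarity(
                em.to_frame(), mode=dissimilarity_mode
            )
            proj = mds_embed(d, k=embed_dims)
            part = partition_fn(proj, k=k)
            tab = cross_tab(data_partition, part)
            p = fisher_exact(tab)
        except Exception as exc:
            raise type(exc)(f"[metric={metric}] {exc}") from exc
        results.append((metric, p, tab))

    adjusted = fdr_adjust([p for _, p, _ in results])
    return [
        AssociationResult(
            metric=metric, method=method, p_raw=p, p_adjusted=pa, table=tab
        )
        for (metric, p, tab), pa in zip(results, adjusted)
    ]
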