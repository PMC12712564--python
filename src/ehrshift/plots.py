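"""Static figure exports: IGT scatters, temporal heatmaps, evaluation matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage

from .dth import TemporalDistribution
from .igt import IGTProjection
from .models import EvalMatrix

__all__ = ["plot_igt", "plot_dth", "plot_eval_matrix", "plot_dendrogram"]


def plot_igt(projection: IGTProjection, path: Path, dims: tuple[int, int] = (0, 1)) -> None:
    """2-D scatter of batch coordinates with a year-gradient color ramp."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x, y = projection.coords[:, dims[0]], projection.coords[:, dims[1]]
    sc = ax.scatter(x, y, c=projection.labels, cmap="viridis", s=60)
    for label, xi, yi in zip(projection.labels, x, y):
        ax.annotate(str(label), (xi, yi), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    fig.colorbar(sc, ax=ax, label="year")
    ax.set_xlabel(f"dim {dims[0] + 1}")
    ax.set_ylabel(f"dim {dims[1] + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dth(dist: TemporalDistribution, path: Path, sqrt: bool = False) -> None:
    """Heatmap of a value × year probability matrix.

    ``sqrt`` applies a square-root transform for display only (useful for
    rare-outcome posteriors); stored values are never transformed.
    """
    values = dist.probs
    if sqrt:
        values = np.sqrt(np.nan_to_num(values))
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(dist.support))))
    im = ax.imshow(values, aspect="auto", cmap="magma")
    ax.set_xticks(range(len(dist.years)), dist.years, rotation=90, fontsize=7)
    ax.set_yticks(range(len(dist.support)), [str(s) for s in dist.support], fontsize=7)
    fig.colorbar(im, ax=ax, label="probability")
    ax.set_title(f"{dist.kind} DTH: {dist.variable}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_eval_matrix(em: EvalMatrix, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(em.values, cmap="RdYlGn", vmin=0, vmax=1)
    ax.set_xticks(range(len(em.labels)), em.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(em.labels)), em.labels, fontsize=7)
    ax.set_xlabel("test year")
    ax.set_ylabel("train year")
    fig.colorbar(im, ax=ax, label=em.metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(projection: IGTProjection, path: Path) -> None:
    z = linkage(projection.coords, method="complete", metric="cityblock")
    fig, ax = plt.subplots(figsize=(6, 4))
    dendrogram(z, labels=[str(l) for l in projection.labels], ax=ax)
    ax.set_ylabel("Manhattan distance (complete linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
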