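"""Mixed-data dimensionality reduction and per-year kernel density maps.

The multivariate branch of the shift characterization compresses the mixed
feature table (numeric age + binary/categorical indicators) into a few latent
dimensions with factorial analysis of mixed data (FAMD): numeric columns are
standardized, categorical columns are expanded into indicators scaled by the
inverse square root of the level proportion and centered, and the processed
matrix is decomposed by SVD. On numeric-only input this reduces exactly to PCA
on the correlation matrix. Yearly Gaussian-kernel densities evaluated on a
common grid over the first dimensions then turn each year into a probability
mass vector, which downstream dissimilarity analysis compares across years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, DimensionError
from .ingest import feature_columns

__all__ = [
    "LatentCoordinates",
    "DensityMap",
    "fit_mixed_reduction",
    "kde_density_map",
    "combine_conditional_maps",
]


@dataclass
class _ColumnSpec:
    name: str
    kind: str  # "numeric" | "categorical"
    mean: float = 0.0
    std: float = 1.0
    levels: list = field(default_factory=list)
    proportions: np.ndarray | None = None


@dataclass
class LatentCoordinates:
    """Fitted reduction: per-admission scores plus projection parameters."""

    coords: np.ndarray  # (n, d)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # processed column × component
    column_specs: list[_ColumnSpec]

    def project(self, features: pd.DataFrame) -> np.ndarray:
        """Out-of-sample projection through the stored scaling parameters."""
        z = _process(features, self.column_specs)
        return z @ self.loadings.to_numpy()


def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_float_dtype(col) and col.nunique() > 2


def _fit_specs(features: pd.DataFrame, cols: list[str]) -> list[_ColumnSpec]:
    specs: list[_ColumnSpec] = []
    for name in cols:
        col = features[name]
        if col.nunique() <= 1:
            warnings.warn(f"dropping constant column {name!r}")
            continue
        if _is_numeric(col):
            specs.append(
                _ColumnSpec(name, "numeric", mean=float(col.mean()),
                            std=float(col.std(ddof=0)))
            )
        else:
            levels = sorted(col.unique().tolist())
            props = np.array([(col == l).mean() for l in levels])
            specs.append(
                _ColumnSpec(name, "categorical", levels=levels, proportions=props)
            )
    return specs


def _process(features: pd.DataFrame, specs: list[_ColumnSpec]) -> np.ndarray:
    """Build the FAMD-processed matrix for the given column specs."""
    blocks = []
    for spec in specs:
        col = features[spec.name]
        if spec.kind == "numeric":
            blocks.append(((col - spec.mean) / spec.std).to_numpy()[:, None])
        else:
            for level, p in zip(spec.levels, spec.proportions):
                ind = (col == level).to_numpy(dtype=float)
                blocks.append((ind / np.sqrt(p) - np.sqrt(p))[:, None])
    return np.hstack(blocks)


def _processed_names(specs: list[_ColumnSpec]) -> list[str]:
    names = []
    for spec in specs:
        if spec.kind == "numeric":
            names.append(spec.name)
        else:
            names.extend(f"{spec.name}={l}" for l in spec.levels)
    return names


def fit_mixed_reduction(features: pd.DataFrame, d: int = 3) -> LatentCoordinates:
    """Fit the FAMD-style reduction and return the first ``d`` score columns.

    Component signs are fixed so each component's largest-magnitude loading is
    positive, making results reproducible across SVD implementations.
    """
    cols = feature_columns(features)
    if len(features) < d + 1:
        raise DimensionError("need at least d+1 admissions")
    specs = _fit_specs(features, cols)
    if not specs:
        raise DimensionError("no usable (non-constant) columns")
    z = _process(features, specs)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if d > rank:
        raise DimensionError(f"d={d} exceeds matrix rank {rank}")
    # flip so each component's largest-magnitude loading is positive
    for k in range(d):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :d] * s[:d]
    evr = (s**2 / (s**2).sum())[:d]
    loadings = pd.DataFrame(
        vt[:d].T, index=_processed_names(specs), columns=[f"dim{k+1}" for k in range(d)]
    )
    return LatentCoordinates(
        coords=scores, explained_variance_ratio=evr,
        loadings=loadings, column_specs=specs,
    )


@dataclass
class DensityMap:
    """Per-year probability mass on a shared grid over the latent space."""

    axes: list[np.ndarray]  # per-dimension grid coordinates
    grid: np.ndarray  # (G, d) flattened grid points
    years: list[int]
    mass: np.ndarray  # (G, n_years), columns sum to 1
    bandwidths: np.ndarray  # (n_years, d)
    bandwidth_rule: str = "scott"

    def year_column(self, year: int) -> np.ndarray:
        return self.mass[:, self.years.index(year)]

    def write(self, path: Path) -> None:
        path = Path(path)
        pd.DataFrame(self.mass, columns=self.years).to_csv(path, index=False)
        sidecar = {
            "axes": [a.tolist() for a in self.axes],
            "bandwidths": self.bandwidths.tolist(),
            "bandwidth_rule": self.bandwidth_rule,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))


def _scott_bandwidth(x: np.ndarray) -> np.ndarray:
    n, d = x.shape
    sigma = x.std(axis=0, ddof=1)
    sigma[sigma == 0] = 1e-6
    return sigma * n ** (-1.0 / (d + 4))


def _product_kde_mass(pts: np.ndarray, axes: list[np.ndarray], h: np.ndarray) -> np.ndarray:
    """Unnormalized Gaussian product-kernel density on the flattened grid.

    Exploits the separability of the product kernel on a regular grid: one
    per-dimension kernel matrix (grid_size × n) per axis, combined by a
    tensor contraction, instead of evaluating every grid point against every
    sample. The flattening order matches ``np.meshgrid(..., indexing="ij")``.
    """
    kmats = [
        np.exp(-0.5 * ((ax[:, None] - pts[None, :, j]) / h[j]) ** 2)
        for j, ax in enumerate(axes)
    ]
    if len(axes) == 1:
        return kmats[0].sum(axis=1)
    if len(axes) == 2:
        return np.einsum("ai,bi->ab", *kmats).ravel()
    return np.einsum("ai,bi,ci->abc", *kmats).ravel()


def kde_density_map(
    coords: LatentCoordinates | np.ndarray,
    years: np.ndarray,
    grid_size: int | None = None,
    bandwidth_rule: str = "scott",
) -> DensityMap:
    """Gaussian product-kernel density per year on a shared grid.

    The grid spans the pooled coordinate range per dimension with a 5% margin;
    ``grid_size`` defaults to 32 points per dimension for d <= 2 and 16 for
    d = 3 to bound the cell count. Each year's density over the grid is
    normalized to total mass 1.
    """
    x = coords.coords if isinstance(coords, LatentCoordinates) else np.asarray(coords)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if d > 3:
        raise DimensionError("density maps support at most 3 dimensions")
    if bandwidth_rule != "scott":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    years = np.asarray(years)
    if len(years) != n:
        raise AlignmentError("year labels must align with coordinates")
    if grid_size is None:
        grid_size = 32 if d <= 2 else 16

    lo, hi = x.min(axis=0), x.max(axis=0)
    margin = 0.05 * (hi - lo)
    axes = [np.linspace(lo[j] - margin[j], hi[j] + margin[j], grid_size)
            for j in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)  # (G, d)

    uniq_years = sorted(int(y) for y in np.unique(years))
    mass = np.empty((grid.shape[0], len(uniq_years)))
    bandwidths = np.empty((len(uniq_years), d))
    for t, year in enumerate(uniq_years):
        pts = x[years == year]
        if len(pts) < 2:
            raise DegenerateInputError(f"year {year} has fewer than 2 points")
        h = _scott_bandwidth(pts)
        bandwidths[t] = h
        dens = _product_kde_mass(pts, axes, h)
        total = dens.sum()
        if total == 0:
            raise DegenerateInputError(f"year {year}: zero density on grid")
        mass[:, t] = dens / total
    return DensityMap(
        axes=axes, grid=grid, years=uniq_years, mass=mass,
        bandwidths=bandwidths, bandwidth_rule=bandwidth_rule,
    )


def combine_conditional_maps(
    maps: dict[int, DensityMap],
    class_weights: dict[int, np.ndarray],
) -> DensityMap:
    """Mix per-class density maps with per-year class weights and renormalize.

    ``class_weights[c]`` is a vector over years (e.g. the class prior per
    year); the output per year is the weighted sum of class maps scaled back
    to total mass 1.
    """
    classes = sorted(maps)
    ref = maps[classes[0]]
    for c in classes[1:]:
        m = maps[c]
        if m.years != ref.years or m.grid.shape != ref.grid.shape or not all(
            np.allclose(a, b) for a, b in zip(m.axes, ref.axes)
        ):
            raise AlignmentError("density maps must share grid and years")
    combined = np.zeros_like(ref.mass)
    for c in classes:
        w = np.asarray(class_weights[c], dtype=float)
        if w.shape != (len(ref.years),):
            raise AlignmentError("class weights must align with years")
        combined += maps[c].mass * w[None, :]
    totals = combined.sum(axis=0, keepdims=True)
    if (totals == 0).any():
        raise DegenerateInputError("zero combined mass in some year")
    return DensityMap(
        axes=ref.axes, grid=ref.grid, years=list(ref.years),
        mass=combined / totals, bandwidths=ref.bandwidths,
        bandwidth_rule=ref.bandwidth_rule,
    )
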