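"""Data temporal heatmaps: per-year estimates of p(x), p(y), p(x|y), p(y|x).

A :class:`TemporalDistribution` is a value-by-year probability matrix — the
data structure behind a temporal heatmap. Marginals detect covariate shift,
the class prior detects prior-probability shift, and the Bayes posterior
p(y|x), derived from the class-conditionals and the prior, isolates concept
shift. Laplace smoothing (default alpha = 0.5, Jeffreys-style) keeps columns
strictly positive ahead of divergence computations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyBatchError

__all__ = [
    "TemporalDistribution",
    "marginal_dth",
    "prior_dth",
    "conditional_dth",
    "posterior_dth",
]

DEFAULT_ALPHA = 0.5
DEFAULT_NUMERIC_BINS = 20


@dataclass
class TemporalDistribution:
    """A value × year probability matrix for one variable.

    ``kind`` is one of ``marginal``, ``prior``, ``conditional`` (with
    ``class_label`` set) or ``posterior``. For the first three, each year
    column sums to 1. For ``posterior`` the support is (value, class) pairs
    and the class block of each value sums to 1 within each year; cells with
    zero evidence are NaN.
    """

    variable: str
    kind: str
    support: list
    years: list[int]
    probs: np.ndarray  # shape (len(support), len(years))
    alpha: float = 0.0
    class_label: object = None
    warnings_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.support), len(self.years)):
            raise ValueError("probability matrix shape mismatch")
        finite = self.probs[np.isfinite(self.probs)]
        if (finite < -1e-12).any():
            raise ValueError("negative probabilities")
        if self.kind in ("marginal", "prior", "conditional"):
            sums = self.probs.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"columns must sum to 1, got {sums}")

    def column_matrix(self) -> np.ndarray:
        """Per-year probability vectors, renormalized for posterior kinds.

        For marginal/prior/conditional this is ``probs`` itself; for a
        posterior the (value, class) cells are normalized within each year so
        the column is a probability vector suitable for dissimilarities.
        """
        if self.kind != "posterior":
            return self.probs
        p = np.nan_to_num(self.probs, nan=0.0)
        totals = p.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        return p / totals

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(
            [str(s) for s in self.support], name="value"
        )
        return pd.DataFrame(self.probs, index=idx, columns=self.years)

    def write(self, path: Path) -> None:
        """CSV matrix plus a JSON sidecar with kind/alpha/variable."""
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = {
            "variable": self.variable,
            "kind": self.kind,
            "alpha": self.alpha,
            "class_label": self.class_label,
            "warnings": self.warnings_log,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, path: Path) -> "TemporalDistribution":
        """Inverse of :meth:`write` for non-posterior kinds."""
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            variable=sidecar["variable"],
            kind=sidecar["kind"],
            support=list(frame.index),
            years=[int(y) for y in frame.columns],
            probs=frame.to_numpy(),
            alpha=sidecar["alpha"],
            class_label=sidecar.get("class_label"),
            warnings_log=sidecar.get("warnings", []),
        )


def _support_and_values(
    batches: list[tuple[int, pd.DataFrame]],
    variable: str,
    bins: int,
) -> tuple[list, list[pd.Series]]:
    """Union support over all years; numeric variables equal-width binned."""
    all_values = pd.concat([b[variable] for _, b in batches], ignore_index=True)
    numeric = pd.api.types.is_float_dtype(all_values) and all_values.nunique() > 2
    if numeric:
        edges = np.linspace(all_values.min(), all_values.max(), bins + 1)
        edges[-1] += 1e-9
        per_year = [
            pd.cut(b[variable], bins=edges, labels=False, include_lowest=True)
            for _, b in batches
        ]
        support = list(range(bins))
    else:
        per_year = [b[variable] for _, b in batches]
        support = sorted(all_values.unique())
    return support, per_year


def marginal_dth(
    batches: list[tuple[int, pd.DataFrame]],
    variable: str,
    alpha: float = DEFAULT_ALPHA,
    bins: int = DEFAULT_NUMERIC_BINS,
) -> TemporalDistribution:
    """Per-year marginal distribution of one feature with Laplace smoothing.

    P[v, t] = (count(v in year t) + alpha) / (n_t + alpha * |support|).
    """
    for year, b in batches:
        if len(b) == 0:
            raise EmptyBatchError(f"year {year} has no rows")
        if variable not in b.columns:
            raise KeyError(f"variable {variable!r} missing in year {year}")
    support, per_year = _support_and_values(batches, variable, bins)
    years = [y for y, _ in batches]
    probs = np.empty((len(support), len(years)))
    for t, values in enumerate(per_year):
        counts = values.value_counts()
        c = np.array([counts.get(v, 0) for v in support], dtype=float)
        probs[:, t] = (c + alpha) / (c.sum() + alpha * len(support))
    return TemporalDistribution(
        variable=variable, kind="marginal", support=support,
        years=years, probs=probs, alpha=alpha,
    )


def prior_dth(batches: list[tuple[int, pd.DataFrame]]) -> TemporalDistribution:
    """Per-year class frequencies of the outcome (2 × n_years)."""
    years = [y for y, _ in batches]
    probs = np.empty((2, len(years)))
    logs: list[str] = []
    for t, (year, b) in enumerate(batches):
        if len(b) == 0:
            raise EmptyBatchError(f"year {year} has no rows")
        p1 = float(b["outcome"].mean())
        if p1 in (0.0, 1.0):
            msg = f"year {year} contains a single outcome class"
            logs.append(msg)
            warnings.warn(msg)
        probs[:, t] = (1.0 - p1, p1)
    return TemporalDistribution(
        variable="outcome", kind="prior", support=[0, 1],
        years=years, probs=probs, warnings_log=logs,
    )


def conditional_dth(
    batches: list[tuple[int, pd.DataFrame]],
    variable: str,
    class_label: int,
    alpha: float = DEFAULT_ALPHA,
    bins: int = DEFAULT_NUMERIC_BINS,
) -> TemporalDistribution:
    """Class-conditional marginal p(x | y = class_label) per year.

    Computed as :func:`marginal_dth` on the class subset of each year but with
    the support fixed by the full cohort, so conditionals across classes share
    an aligned support. Years where the class is absent get the uniform
    smoothed column (alpha > 0) and a warning.
    """
    support, per_year = _support_and_values(batches, variable, bins)
    years = [y for y, _ in batches]
    probs = np.empty((len(support), len(years)))
    logs: list[str] = []
    for t, (year_batch, values) in enumerate(zip(batches, per_year)):
        year, b = year_batch
        mask = (b["outcome"] == class_label).to_numpy()
        if not mask.any():
            msg = f"class {class_label} absent in year {year}"
            logs.append(msg)
            warnings.warn(msg)
        counts = values[mask].value_counts()
        c = np.array([counts.get(v, 0) for v in support], dtype=float)
        denom = c.sum() + alpha * len(support)
        if denom == 0:
            raise EmptyBatchError(
                f"year {year}: empty class subset with alpha=0"
            )
        probs[:, t] = (c + alpha) / denom
    return TemporalDistribution(
        variable=variable, kind="conditional", support=support, years=years,
        probs=probs, alpha=alpha, class_label=class_label, warnings_log=logs,
    )


def posterior_dth(
    conditionals: dict[int, TemporalDistribution],
    prior: TemporalDistribution,
) -> TemporalDistribution:
    """Bayes posterior p(y = c | x = v, t) from class-conditionals and prior.

    P[c | v, t] = p(v | c, t) p(c, t) / sum_c' p(v | c', t) p(c', t).
    The support is the cross product (value, class); cells whose denominator is
    zero carry NaN (no evidence for that value in that year).
    """
    classes = sorted(conditionals)
    ref = conditionals[classes[0]]
    for c in classes[1:]:
        other = conditionals[c]
        if other.support != ref.support or other.years != ref.years:
            raise AlignmentError("conditionals must share support and years")
    if prior.years != ref.years:
        raise AlignmentError("prior years do not match conditionals")
    prior_rows = {c: prior.support.index(c) for c in classes}

    n_v, n_t = len(ref.support), len(ref.years)
    joint = np.stack(
        [conditionals[c].probs * prior.probs[prior_rows[c], :] for c in classes]
    )  # (class, value, year)
    denom = joint.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(denom > 0, joint / denom, np.nan)

    support = [(v, c) for v in ref.support for c in classes]
    probs = np.empty((n_v * len(classes), n_t))
    for vi in range(n_v):
        for ci in range(len(classes)):
            probs[vi * len(classes) + ci, :] = post[ci, vi, :]
    return TemporalDistribution(
        variable=ref.variable, kind="posterior", support=support,
        years=ref.years, probs=probs, alpha=ref.alpha,
    )
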