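"""Yearly predictive models and their interyear evaluation matrices.

One classifier (random forest or gradient boosting) is trained per yearly
batch on a stratified 80/20 train/test split, with 30% of the training side
held out for validation (so 56/24/20 of the year overall). A single
hyperparameter configuration is chosen for the whole series by averaging
same-year validation ROC-AUC across the yearly models over a grid. Each
model's decision threshold is picked by the Youden index
(J = sensitivity + specificity − 1) on the most recent year's validation
predictions, and every model is then evaluated on every year's held-out test
set, producing a train-year × test-year matrix per metric.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, SplitError, ThresholdError
from .ingest import feature_columns

__all__ = [
    "METRICS",
    "YearlySplit",
    "ModelSet",
    "EvalMatrix",
    "make_splits",
    "select_hyperparameters",
    "fit_models",
    "youden_threshold",
    "interyear_evaluation",
    "DEFAULT_GRIDS",
]

METRICS = ("roc_auc", "pr_auc", "precision", "recall", "accuracy", "macro_f1")

#: Default hyperparameter grids; they include the reference configurations
#: (random forest: 500 trees, depth 9; gradient boosting: 100 estimators,
#: depth 2) among the candidates.
DEFAULT_GRIDS = {
    "random_forest": [
        {"n_estimators": n, "max_depth": d}
        for n in (100, 300, 500)
        for d in (3, 6, 9)
    ],
    "gradient_boosting": [
        {"n_estimators": n, "max_depth": d}
        for n in (50, 100)
        for d in (1, 2, 3)
    ],
}

TEST_FRACTION = 0.20
VALIDATION_FRACTION = 0.30  # of the non-test 80%


def _fit_seed(seed: int, year: int, params: dict) -> int:
    """Stable per-fit seed derived from (seed, year, grid point)."""
    key = f"{seed}|{year}|{sorted(params.items())}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class YearlySplit:
    """Per-year disjoint train/validation/test row positions."""

    indices: dict[int, dict[str, np.ndarray]]  # year -> {train, val, test}
    seed: int

    def rows(self, year: int, part: str) -> np.ndarray:
        return self.indices[year][part]


@dataclass
class ThresholdRecord:
    candidates: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    chosen: float
    source_year: int


@dataclass
class ModelSet:
    """Fitted per-year classifiers with shared hyperparameters."""

    algorithm: str
    params: dict
    models: dict[int, object]
    thresholds: dict[int, float] = field(default_factory=dict)
    threshold_records: dict[int, ThresholdRecord] = field(default_factory=dict)
    grid_scores: pd.DataFrame | None = None

    def metadata(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": self.params,
            "thresholds": {int(y): float(t) for y, t in self.thresholds.items()},
        }


@dataclass
class EvalMatrix:
    """Train-year × test-year matrix of one performance metric."""

    metric: str
    labels: list[int]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index_label="train_year")


def make_splits(batches: list[tuple[int, pd.DataFrame]], seed: int) -> YearlySplit:
    """Stratified 56/24/20 train/validation/test split within each year."""
    indices: dict[int, dict[str, np.ndarray]] = {}
    for year, b in batches:
        y = b["outcome"].to_numpy()
        if len(b) < 25:
            raise SplitError(f"year {year} has fewer than 25 rows")
        if len(np.unique(y)) < 2:
            raise SplitError(f"year {year} is missing an outcome class")
        rows = np.arange(len(b))
        trainval, test = train_test_split(
            rows, test_size=TEST_FRACTION, stratify=y, random_state=seed % (2**31)
        )
        train, val = train_test_split(
            trainval,
            test_size=VALIDATION_FRACTION,
            stratify=y[trainval],
            random_state=(seed + 1) % (2**31),
        )
        indices[year] = {
            "train": np.sort(train),
            "val": np.sort(val),
            "test": np.sort(test),
        }
    return YearlySplit(indices=indices, seed=seed)


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def _xy(batch: pd.DataFrame, rows: np.ndarray, cols: list[str]):
    return batch.iloc[rows][cols].to_numpy(dtype=float), batch.iloc[rows][
        "outcome"
    ].to_numpy()


def select_hyperparameters(
    batches: list[tuple[int, pd.DataFrame]],
    splits: YearlySplit,
    algorithm: str,
    grid: list[dict] | None = None,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Grid search shared across years by mean same-year validation ROC-AUC.

    Ties are broken toward the smaller model: fewer trees first, then
    shallower depth. Years whose validation set degenerates to one class are
    excluded from the mean with a warning. Returns (best params, score table).
    """
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid
    if not grid:
        raise ConfigurationError("hyperparameter grid is empty")
    cols = feature_columns(batches[0][1])
    records = []
    for params in grid:
        scores = []
        for year, b in batches:
            xt, yt = _xy(b, splits.rows(year, "train"), cols)
            xv, yv = _xy(b, splits.rows(year, "val"), cols)
            if len(np.unique(yv)) < 2:
                import warnings

                warnings.warn(f"year {year}: single-class validation set skipped")
                continue
            est = _make_estimator(algorithm, params, _fit_seed(seed, year, params))
            est.fit(xt, yt)
            scores.append(roc_auc_score(yv, est.predict_proba(xv)[:, 1]))
        records.append({**params, "mean_val_roc_auc": float(np.mean(scores))})
    table = pd.DataFrame(records)
    best = table.sort_values(
        ["mean_val_roc_auc", "n_estimators", "max_depth"],
        ascending=[False, True, True],
    ).iloc[0]
    chosen = {k: int(best[k]) for k in grid[0]}
    return chosen, table


def youden_threshold(
    scores: np.ndarray, labels: np.ndarray, source_year: int = -1
) -> ThresholdRecord:
    """Pick the score cut maximizing J = sensitivity + specificity − 1.

    Candidates are the distinct predicted scores; a prediction is positive
    when score >= candidate. Ties on J resolve to the smallest candidate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ThresholdError("threshold selection needs both classes")
    candidates = np.unique(scores)
    pos, neg = labels == 1, labels == 0
    sens = np.array([(scores[pos] >= c).mean() for c in candidates])
    spec = np.array([(scores[neg] < c).mean() for c in candidates])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return ThresholdRecord(
        candidates=candidates, sensitivity=sens, specificity=spec,
        youden=j, chosen=float(candidates[best]), source_year=source_year,
    )


def fit_models(
    batches: list[tuple[int, pd.DataFrame]],
    splits: YearlySplit,
    algorithm: str,
    params: dict,
    seed: int = 0,
    threshold_mode: str = "per_model",
) -> ModelSet:
    """Fit one classifier per year and select its decision threshold.

    Thresholds come from the most recent year's validation data. With
    ``threshold_mode="per_model"`` (default) each model is scored on that
    validation set itself; ``"global"`` reuses the most recent year's own
    model threshold for every model.
    """
    cols = feature_columns(batches[0][1])
    models: dict[int, object] = {}
    for year, b in batches:
        xt, yt = _xy(b, splits.rows(year, "train"), cols)
        est = _make_estimator(algorithm, params, _fit_seed(seed, year, params))
        est.fit(xt, yt)
        models[year] = est

    last_year, last_batch = batches[-1]
    xv, yv = _xy(last_batch, splits.rows(last_year, "val"), cols)
    mset = ModelSet(algorithm=algorithm, params=dict(params), models=models)
    if threshold_mode == "global":
        record = youden_threshold(
            models[last_year].predict_proba(xv)[:, 1], yv, last_year
        )
        for year in models:
            mset.thresholds[year] = record.chosen
            mset.threshold_records[year] = record
    elif threshold_mode == "per_model":
        for year, est in models.items():
            record = youden_threshold(est.predict_proba(xv)[:, 1], yv, last_year)
            mset.thresholds[year] = record.chosen
            mset.threshold_records[year] = record
    else:
        raise ConfigurationError(f"unknown threshold_mode {threshold_mode!r}")
    return mset


def _metric_value(
    metric: str, y: np.ndarray, proba: np.ndarray, threshold: float
) -> float:
    if metric in ("roc_auc", "pr_auc") and len(np.unique(y)) < 2:
        return float("nan")  # undefined, not zero
    if metric == "roc_auc":
        return float(roc_auc_score(y, proba))
    if metric == "pr_auc":
        return float(average_precision_score(y, proba))
    pred = (proba >= threshold).astype(int)
    if metric == "precision":
        return float(precision_score(y, pred, zero_division=0))
    if metric == "recall":
        return float(recall_score(y, pred, zero_division=0))
    if metric == "accuracy":
        return float(accuracy_score(y, pred))
    if metric == "macro_f1":
        return float(f1_score(y, pred, average="macro", zero_division=0))
    raise ConfigurationError(f"unknown metric {metric!r}")


def interyear_evaluations(
    models: ModelSet,
    batches: list[tuple[int, pd.DataFrame]],
    splits: YearlySplit,
    metrics: tuple[str, ...] = METRICS,
) -> dict[str, EvalMatrix]:
    """All requested metrics' train-year × test-year matrices at once.

    Predicted probabilities are computed once per (model, test year) and
    reused across metrics.
    """
    cols = feature_columns(batches[0][1])
    years = [y for y, _ in batches]
    tests = {year: _xy(b, splits.rows(year, "test"), cols) for year, b in batches}
    # one prediction pass per model over the concatenated test sets
    x_all = np.vstack([tests[y][0] for y in years])
    bounds = np.cumsum([0] + [len(tests[y][1]) for y in years])
    values = {m: np.empty((len(years), len(years))) for m in metrics}
    for i, yi in enumerate(years):
        est = models.models[yi]
        thr = models.thresholds.get(yi, 0.5)
        proba_all = est.predict_proba(x_all)[:, 1]
        for j, yj in enumerate(years):
            proba = proba_all[bounds[j]:bounds[j + 1]]
            yte = tests[yj][1]
            for m in metrics:
                values[m][i, j] = _metric_value(m, yte, proba, thr)
    return {
        m: EvalMatrix(metric=m, labels=years, values=values[m]) for m in metrics
    }


def interyear_evaluation(
    models: ModelSet,
    batches: list[tuple[int, pd.DataFrame]],
    splits: YearlySplit,
    metric: str,
) -> EvalMatrix:
    """M[i, j] = metric of the year-i model on year j's held-out test rows."""
    return interyear_evaluations(models, batches, splits, (metric,))[metric]
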