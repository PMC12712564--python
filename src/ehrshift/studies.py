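"""Replicate harness for simulation studies over the full pipeline.

One replicate = simulate a scenario at one seed, characterize the data shift,
train yearly models, and run the association tests. The two study designs the
package validates itself with are:

* changepoint recovery — combined covariate+concept scenarios: does the
  2-cluster partition of the data IGT split the years exactly at the
  changepoint, and does the interyear ROC-AUC matrix show better transfer
  within coding periods than across them?
* null calibration — no-shift scenarios: how often do the Fisher association
  tests reject at .05 when there is nothing to find?
"""

from __future__ import annotations

import numpy as np

from . import association as assoc
from .igt import js_dissimilarity, mds_embed
from .ingest import CodeMap, batch_by_year, harmonize_codes
from .models import METRICS, fit_models, interyear_evaluations, make_splits
from .pipeline import characterize_data_shift
from .synthetic import default_code_map, default_scenario, generate_cohort

__all__ = ["shift_replicate", "within_cross_gap"]

DEFAULT_MODEL_PARAMS = {"n_estimators": 100, "max_depth": 6}


def within_cross_gap(values: np.ndarray, labels: list[int], changepoint: int) -> float:
    """Mean within-period cell minus mean cross-period cell of an interyear matrix."""
    labels = np.asarray(labels)
    post = labels >= changepoint
    pre = ~post
    within = np.r_[
        values[np.ix_(pre, pre)].ravel(), values[np.ix_(post, post)].ravel()
    ]
    cross = np.r_[
        values[np.ix_(pre, post)].ravel(), values[np.ix_(post, pre)].ravel()
    ]
    return float(np.nanmean(within) - np.nanmean(cross))


def shift_replicate(
    kind: str,
    seed: int,
    n_per_year: int,
    algorithm: str = "random_forest",
    model_params: dict | None = None,
    methods: tuple[str, ...] = ("hierarchical", "kmeans"),
    metrics: tuple[str, ...] = METRICS,
) -> dict:
    """Run one full simulate→characterize→model→associate replicate.

    Returns the per-method/per-metric raw Fisher p-values, whether the
    hierarchical 2-cluster partition of the data IGT splits exactly at the
    scenario changepoint, and the within-minus-cross ROC-AUC gap (NaN for
    scenarios without a changepoint).
    """
    scenario = default_scenario(kind, n_per_year=n_per_year, seed=seed)
    table = generate_cohort(scenario)
    code_map = CodeMap(default_code_map())
    features = harmonize_codes(table, code_map)
    batches = batch_by_year(features)

    char = characterize_data_shift(batches, features)
    igt_cov = char["igt_covariate"]
    hier_part = assoc.hierarchical_partition(igt_cov, k=2)

    if scenario.changepoint_year is not None:
        expected = {y: int(y >= scenario.changepoint_year) for y in scenario.years}
        split_exact = hier_part.labels == expected
    else:
        split_exact = None

    splits = make_splits(batches, seed=seed)
    mset = fit_models(
        batches, splits, algorithm, model_params or DEFAULT_MODEL_PARAMS, seed=seed
    )
    eval_matrices = interyear_evaluations(mset, batches, splits, metrics)

    roc_gap = float("nan")
    if scenario.changepoint_year is not None:
        em = eval_matrices["roc_auc"]
        roc_gap = within_cross_gap(
            em.values, em.labels, scenario.changepoint_year
        )

    p_raw: dict[str, dict[str, float]] = {}
    for method in methods:
        part = (
            hier_part
            if method == "hierarchical"
            else assoc.kmeans_partition(igt_cov, k=2)
        )
        results = assoc.associate(part, eval_matrices, method=method)
        p_raw[method] = {r.metric: r.p_raw for r in results}

    return {
        "scenario": scenario,
        "data_partition": hier_part,
        "changepoint_split_exact": split_exact,
        "roc_auc_gap": roc_gap,
        "p_raw": p_raw,
        "eval_matrices": eval_matrices,
        "igt_covariate": igt_cov,
    }
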