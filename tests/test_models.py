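"""Split geometry, threshold selection, grid search, interyear evaluation."""

import numpy as np
import pytest

from ehrshift.errors import SplitError, ThresholdError
from ehrshift.ingest import batch_by_year
from ehrshift.models import (
    DEFAULT_GRIDS,
    METRICS,
    fit_models,
    interyear_evaluations,
    make_splits,
    select_hyperparameters,
    youden_threshold,
)
from tests.conftest import toy_feature_table


@pytest.fixture(scope="module")
def separable_batches():
    return batch_by_year(toy_feature_table(n_per_year=120, pattern="separable", seed=2))


class TestSplits:
    def test_fraction_arithmetic_on_100_rows(self):
        batches = batch_by_year(toy_feature_table(n_per_year=100, seed=1))
        splits = make_splits(batches, seed=0)
        for year in splits.indices:
            n_train = len(splits.rows(year, "train"))
            n_val = len(splits.rows(year, "val"))
            n_test = len(splits.rows(year, "test"))
            assert n_test == 20
            assert abs(n_val - 24) <= 1
            assert abs(n_train - 56) <= 1
            assert n_train + n_val + n_test == 100

    def test_parts_disjoint_and_exhaustive(self, separable_batches):
        splits = make_splits(separable_batches, seed=5)
        for year, b in separable_batches:
            parts = [set(splits.rows(year, p)) for p in ("train", "val", "test")]
            assert sum(len(p) for p in parts) == len(b)
            assert set().union(*parts) == set(range(len(b)))

    def test_stratification_preserves_prevalence(self, separable_batches):
        splits = make_splits(separable_batches, seed=5)
        for year, b in separable_batches:
            y = b["outcome"].to_numpy()
            overall = y.mean()
            for part in ("train", "val", "test"):
                rows = splits.rows(year, part)
                assert abs(y[rows].sum() - overall * len(rows)) <= 1

    def test_same_seed_identical_indices(self, separable_batches):
        a = make_splits(separable_batches, seed=9)
        b = make_splits(separable_batches, seed=9)
        for year in a.indices:
            for part in ("train", "val", "test"):
                np.testing.assert_array_equal(a.rows(year, part), b.rows(year, part))

    def test_single_class_year_rejected(self):
        df = toy_feature_table(n_per_year=60)
        df.loc[df.year == 2009, "outcome"] = 0
        with pytest.raises(SplitError, match="2009"):
            make_splits(batch_by_year(df), seed=0)


class TestYouden:
    def test_separated_scores_by_exhaustive_oracle(self):
        rec = youden_threshold(
            np.array([0.2, 0.3, 0.6, 0.9]), np.array([0, 0, 1, 1])
        )
        assert rec.chosen == 0.6
        assert rec.youden.max() == pytest.approx(1.0)
        # oracle: exhaustive candidate evaluation
        for c, s, p, j in zip(rec.candidates, rec.sensitivity, rec.specificity,
                              rec.youden):
            assert j == pytest.approx(s + p - 1.0)

    def test_anti_separated_scores_reach_j_zero(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([0, 0, 1, 1])
        rec = youden_threshold(scores, labels)
        # brute force over candidates: J(c) = sens(c) + spec(c) - 1
        brute = max(
            (scores[labels == 1] >= c).mean() + (scores[labels == 0] < c).mean() - 1
            for c in np.unique(scores)
        )
        assert rec.youden.max() == pytest.approx(brute)
        assert rec.youden.max() == pytest.approx(0.0)

    def test_duplication_invariance(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 1, 0, 1])
        a = youden_threshold(scores, labels)
        b = youden_threshold(np.r_[scores, scores], np.r_[labels, labels])
        assert a.chosen == b.chosen

    def test_single_class_rejected(self):
        with pytest.raises(ThresholdError):
            youden_threshold(np.array([0.1, 0.2]), np.array([1, 1]))


class TestGridSearch:
    def test_underfit_never_beats_adequate_model(self):
        batches = batch_by_year(
            toy_feature_table(n_per_year=120, pattern="xor", seed=2)
        )
        splits = make_splits(batches, seed=3)
        grid = [
            {"n_estimators": 2, "max_depth": 1},
            {"n_estimators": 50, "max_depth": 4},
        ]
        chosen, table = select_hyperparameters(
            batches, splits, "random_forest", grid, seed=3
        )
        assert chosen == {"n_estimators": 50, "max_depth": 4}
        assert table.shape[0] == 2

    def test_single_point_grid_returned_unchanged(self, separable_batches):
        splits = make_splits(separable_batches, seed=3)
        chosen, _ = select_hyperparameters(
            separable_batches, splits, "random_forest",
            [{"n_estimators": 5, "max_depth": 2}], seed=3,
        )
        assert chosen == {"n_estimators": 5, "max_depth": 2}

    def test_reference_settings_are_expressible_grid_points(self):
        assert {"n_estimators": 500, "max_depth": 9} in DEFAULT_GRIDS["random_forest"]
        assert {"n_estimators": 100, "max_depth": 2} in DEFAULT_GRIDS[
            "gradient_boosting"
        ]


class TestInteryearEvaluation:
    def test_separable_cohort_has_perfect_roc_auc_everywhere(self, separable_batches):
        splits = make_splits(separable_batches, seed=4)
        mset = fit_models(
            separable_batches, splits, "random_forest",
            {"n_estimators": 20, "max_depth": 3}, seed=4,
        )
        em = interyear_evaluations(mset, separable_batches, splits, ("roc_auc",))[
            "roc_auc"
        ]
        np.testing.assert_allclose(em.values, 1.0)

    def test_all_metrics_bounded(self, separable_batches):
        splits = make_splits(separable_batches, seed=4)
        mset = fit_models(
            separable_batches, splits, "gradient_boosting",
            {"n_estimators": 10, "max_depth": 2}, seed=4,
        )
        ems = interyear_evaluations(mset, separable_batches, splits, METRICS)
        for em in ems.values():
            vals = em.values[np.isfinite(em.values)]
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_no_leakage_between_train_and_test_indices(self, separable_batches):
        splits = make_splits(separable_batches, seed=4)
        for year in splits.indices:
            train = set(splits.rows(year, "train")) | set(splits.rows(year, "val"))
            assert not train & set(splits.rows(year, "test"))

    def test_thresholds_recorded_and_in_range(self, separable_batches):
        splits = make_splits(separable_batches, seed=4)
        mset = fit_models(
            separable_batches, splits, "random_forest",
            {"n_estimators": 20, "max_depth": 3}, seed=4,
        )
        last_year = separable_batches[-1][0]
        for year, thr in mset.thresholds.items():
            assert 0 < thr < 1
            assert mset.threshold_records[year].source_year == last_year
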