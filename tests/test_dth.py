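"""Temporal distribution estimates: smoothing, conditioning, Bayes inversion."""

import numpy as np
import pandas as pd
import pytest

from ehrshift.dth import (
    TemporalDistribution,
    conditional_dth,
    marginal_dth,
    posterior_dth,
    prior_dth,
)
from ehrshift.errors import AlignmentError, EmptyBatchError


def _batches_from_counts(counts_by_year):
    """Build yearly batches with exact categorical counts for one variable."""
    batches = []
    for year, counts in counts_by_year.items():
        values, outcome = [], []
        for v, (n0, n1) in counts.items():
            values += [v] * (n0 + n1)
            outcome += [0] * n0 + [1] * n1
        batches.append(
            (year, pd.DataFrame({"x": values, "outcome": outcome, "year": year}))
        )
    return batches


class TestMarginal:
    def test_uniform_counts_no_smoothing(self):
        batches = _batches_from_counts({2008: {"A": (2, 0), "B": (2, 0)},
                                        2009: {"A": (1, 0), "B": (3, 0)}})
        d = marginal_dth(batches, "x", alpha=0)
        np.testing.assert_allclose(d.probs[:, 0], [0.5, 0.5])
        np.testing.assert_allclose(d.probs[:, 1], [0.25, 0.75])

    def test_laplace_smoothing_by_hand(self):
        # counts {A:4, B:0}, alpha=1, |support|=2 -> (5/6, 1/6)
        batches = _batches_from_counts({2008: {"A": (4, 0)},
                                        2009: {"A": (1, 0), "B": (1, 0)}})
        d = marginal_dth(batches, "x", alpha=1)
        np.testing.assert_allclose(d.probs[:, 0], [5 / 6, 1 / 6])

    def test_columns_sum_to_one(self, null_batches):
        d = marginal_dth(null_batches, "age", alpha=0.5)
        np.testing.assert_allclose(d.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_batch_rejected(self):
        batches = [(2008, pd.DataFrame({"x": [], "outcome": []}))]
        with pytest.raises(EmptyBatchError):
            marginal_dth(batches, "x")

    def test_csv_round_trip(self, null_batches, tmp_path):
        d = marginal_dth(null_batches, "chapter::Neoplasms", alpha=0.5)
        d.write(tmp_path / "m.csv")
        from ehrshift.dth import TemporalDistribution

        back = TemporalDistribution.read(tmp_path / "m.csv")
        np.testing.assert_allclose(back.probs, d.probs)
        assert back.years == d.years and back.kind == d.kind

    def test_year_permutation_permutes_columns(self, null_batches):
        d = marginal_dth(null_batches, "chapter::Neoplasms")
        perm = list(reversed(null_batches))
        dp = marginal_dth(perm, "chapter::Neoplasms")
        np.testing.assert_allclose(dp.probs, d.probs[:, ::-1])


class TestPrior:
    def test_class_frequencies(self):
        batches = _batches_from_counts({2008: {"A": (97, 3)}, 2009: {"A": (90, 10)}})
        d = prior_dth(batches)
        np.testing.assert_allclose(d.probs[:, 0], [0.97, 0.03])
        np.testing.assert_allclose(d.probs[:, 1], [0.90, 0.10])

    def test_null_cohort_prior_is_stable(self, null_batches):
        d = prior_dth(null_batches)
        death = d.probs[1]
        n = len(null_batches[0][1])
        se = np.sqrt(0.0291 * (1 - 0.0291) / n)
        assert death.max() - death.min() <= 6 * se

    def test_single_class_year_warns_but_emits(self):
        batches = _batches_from_counts({2008: {"A": (5, 0)}, 2009: {"A": (4, 1)}})
        with pytest.warns(UserWarning, match="single outcome class"):
            d = prior_dth(batches)
        np.testing.assert_allclose(d.probs[:, 0], [1.0, 0.0])


class TestConditional:
    def test_independent_feature_conditional_matches_marginal(self):
        rng = np.random.default_rng(4)
        batches = []
        for year in (2008, 2009, 2010):
            n = 4000
            batches.append(
                (year, pd.DataFrame({
                    "x": rng.integers(0, 2, n),
                    "outcome": (rng.random(n) < 0.3).astype(int),
                    "year": year,
                }))
            )
        marg = marginal_dth(batches, "x", alpha=0)
        cond = conditional_dth(batches, "x", class_label=1, alpha=0)
        tv = 0.5 * np.abs(marg.probs - cond.probs).sum(axis=0)
        assert tv.max() < 0.03

    def test_empty_class_subset_gives_uniform_smoothed_column(self):
        batches = _batches_from_counts({2008: {"A": (3, 0), "B": (2, 0)},
                                        2009: {"A": (2, 1), "B": (2, 0)}})
        with pytest.warns(UserWarning, match="absent"):
            d = conditional_dth(batches, "x", class_label=1, alpha=0.5)
        np.testing.assert_allclose(d.probs[:, 0], [0.5, 0.5])

    def test_columns_sum_to_one(self, null_batches):
        d = conditional_dth(null_batches, "chapter::Neoplasms", class_label=1)
        np.testing.assert_allclose(d.probs.sum(axis=0), 1.0, atol=1e-9)


class TestPosterior:
    def _simple(self, p1=0.2, p0=0.1, prior1=0.0291):
        years = [2008]
        c1 = TemporalDistribution("x", "conditional", [0, 1], years,
                                  np.array([[1 - p1], [p1]]), class_label=1)
        c0 = TemporalDistribution("x", "conditional", [0, 1], years,
                                  np.array([[1 - p0], [p0]]), class_label=0)
        prior = TemporalDistribution("outcome", "prior", [0, 1], years,
                                     np.array([[1 - prior1], [prior1]]))
        return {0: c0, 1: c1}, prior

    def test_hand_bayes_value(self):
        conds, prior = self._simple()
        post = posterior_dth(conds, prior)
        # p(y=1 | x=1) = .2*.0291 / (.2*.0291 + .1*.9709) = 0.056554...
        idx = post.support.index((1, 1))
        assert post.probs[idx, 0] == pytest.approx(0.0566, abs=1e-4)

    def test_equal_conditionals_reduce_to_prior(self):
        conds, prior = self._simple(p1=0.3, p0=0.3)
        post = posterior_dth(conds, prior)
        for v in (0, 1):
            assert post.probs[post.support.index((v, 1)), 0] == pytest.approx(0.0291)

    def test_class_probabilities_sum_to_one_per_value(self, null_batches):
        prior = prior_dth(null_batches)
        conds = {
            c: conditional_dth(null_batches, "chapter::Neoplasms", c, alpha=0.5)
            for c in (0, 1)
        }
        post = posterior_dth(conds, prior)
        values = {v for v, _ in post.support}
        for v in values:
            rows = [post.support.index((v, c)) for c in (0, 1)]
            sums = post.probs[rows].sum(axis=0)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_law_of_total_probability_exact_at_alpha_zero(self, null_batches):
        var = "chapter::Diseases of the circulatory system"
        prior = prior_dth(null_batches)
        marg = marginal_dth(null_batches, var, alpha=0)
        conds = {c: conditional_dth(null_batches, var, c, alpha=0) for c in (0, 1)}
        recon = sum(
            conds[c].probs * prior.probs[prior.support.index(c)] for c in (0, 1)
        )
        np.testing.assert_allclose(recon, marg.probs, atol=1e-12)

    def test_mismatched_support_rejected(self):
        conds, prior = self._simple()
        bad = TemporalDistribution("x", "conditional", [0, 1, 2], [2008],
                                   np.array([[0.5], [0.3], [0.2]]), class_label=0)
        with pytest.raises(AlignmentError):
            posterior_dth({0: bad, 1: conds[1]}, prior)
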