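"""Dual-correlation scoring, the sign-conflict rule, and top-k ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from oracle_helpers import oracle_rank
from conftest import random_correlation_instance
from frailmark.ranking import (
    CorrelationRanker, combined_score, correlate, rank_candidates, run_all,
)


class TestCorrelate:
    def test_perfect_linear_relation(self):
        p, s, n, flag = correlate([1, 2, 3], [2, 4, 6])
        assert (p, s, n, flag) == (pytest.approx(1.0), pytest.approx(1.0), 3, "ok")

    def test_outlier_splits_pearson_and_spearman_signs(self):
        # one large outlier drives Pearson negative while ranks rise:
        # sum of squared rank differences is 12, so rho = 1 - 72/120 = 0.4
        p, s, _, _ = correlate([1, 2, 3, 4, 5], [0, 100, 3, 4, 5])
        assert p == pytest.approx(-0.313, abs=5e-4)
        assert s == pytest.approx(0.4)

    def test_constant_vector_flagged(self):
        p, s, _, flag = correlate([1, 2, 3], [5, 5, 5])
        assert np.isnan(p) and np.isnan(s) and flag == "constant_gene"

    def test_insufficient_pairs_after_deletion(self):
        p, s, n, flag = correlate([1, np.nan, 3, np.nan], [1, 2, np.nan, 4])
        assert flag == "insufficient_n" and n == 1 and np.isnan(p)

    def test_ties_get_average_ranks(self):
        _, s, _, _ = correlate([1, 2, 2, 3], [1, 2, 3, 4])
        rho = stats.spearmanr([1, 2, 2, 3], [1, 2, 3, 4]).statistic
        assert s == pytest.approx(rho)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.1, 50), st.floats(-100, 100))
    def test_pearson_invariant_under_positive_affine_maps(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p0, s0, _, _ = correlate(x, y)
        p1, s1, _, _ = correlate(a * x + b, y)
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert s1 == pytest.approx(s0, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_spearman_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        _, s0, _, _ = correlate(x, y)
        _, s1, _, _ = correlate(np.exp(x), y)  # strictly increasing
        assert s1 == pytest.approx(s0, abs=1e-12)


class TestCombinedScore:
    def test_sign_conflict_gives_zero(self):
        assert combined_score(-0.313, 0.4) == 0.0

    def test_agreement_takes_smaller_magnitude(self):
        assert combined_score(0.8, 0.6) == pytest.approx(0.6)
        assert combined_score(-0.7, -0.9) == pytest.approx(-0.7)

    def test_zero_or_undefined_inputs(self):
        assert combined_score(0.0, 0.5) == 0.0
        assert combined_score(0.5, 0.0) == 0.0
        assert combined_score(np.nan, 0.5) == 0.0
        assert combined_score(0.5, np.nan) == 0.0

    def test_alternative_modes(self):
        assert combined_score(0.8, 0.6, mode="mean") == pytest.approx(0.7)
        assert combined_score(-0.8, -0.6, mode="pearson") == pytest.approx(-0.8)
        with pytest.raises(ValueError):
            combined_score(0.5, 0.5, mode="median")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_sign_consensus_property(self, p, s):
        c = combined_score(p, s)
        if p * s <= 0:
            assert c == 0.0
        else:
            assert np.sign(c) == np.sign(p) == np.sign(s)
            assert abs(c) == pytest.approx(min(abs(p), abs(s)))


class TestRankCandidates:
    def _stratum(self, rng, n=200, n_null=4, planted_r=0.9):
        samples = [f"s{i}" for i in range(n)]
        y = rng.normal(4.2, 1.0, n)
        z = (y - y.mean()) / y.std()
        a = planted_r / np.sqrt(1 - planted_r**2)
        rows = {"gPLANT": a * z + rng.normal(size=n)}
        for i in range(n_null):
            rows[f"gN{i}"] = rng.normal(size=n)
        expr = pd.DataFrame(rows).T
        expr.columns = samples
        cohort = pd.DataFrame(
            {"sex": "F", "age_group": "old", "gait4": y, "walk400": np.nan, "chair5": np.nan},
            index=samples,
        )
        return expr, cohort

    def test_planted_gene_ranks_first(self, rng):
        expr, cohort = self._stratum(rng)
        rl = rank_candidates(expr, cohort, "F", "gait4", expr.index, k=3)
        assert rl.entries[0].gene_id == "gPLANT"
        assert rl.entries[0].combined_score > 0.7

    def test_all_constant_genes_give_empty_list(self):
        samples = [f"s{i}" for i in range(10)]
        expr = pd.DataFrame(np.ones((4, 10)), index=list("abcd"), columns=samples)
        cohort = pd.DataFrame(
            {"sex": "F", "age_group": "old", "gait4": np.arange(10.0)}, index=samples
        )
        rl = rank_candidates(expr, cohort, "F", "gait4", expr.index, k=40)
        assert len(rl) == 0

    def test_k_larger_than_nonzero_genes_truncates(self, rng):
        expr, cohort = self._stratum(rng, n=30, n_null=2)
        rl = rank_candidates(expr, cohort, "F", "gait4", expr.index, k=40)
        assert len(rl) <= 3
        assert all(e.combined_score != 0 for e in rl.entries)

    def test_missing_candidate_raises_lookup_error(self, rng):
        expr, cohort = self._stratum(rng, n=20)
        with pytest.raises(KeyError, match="gMISSING"):
            rank_candidates(expr, cohort, "F", "gait4", ["gPLANT", "gMISSING"], k=5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            expr, cohort = random_correlation_instance(rng)
            rl = rank_candidates(expr, cohort, "F", "gait4", expr.index, k=10)
            expected = oracle_rank(expr, cohort["gait4"], k=10)
            assert rl.gene_ids() == [g for g, *_ in expected]
            for entry, (_, c, p, s) in zip(rl.entries, expected):
                assert entry.combined_score == pytest.approx(c, abs=1e-12)
                assert entry.pearson_r == pytest.approx(p, abs=1e-12)
                assert entry.spearman_rho == pytest.approx(s, abs=1e-12)

    def test_scores_non_increasing(self, rng):
        expr, cohort = random_correlation_instance(rng, n_genes=30, n_samples=20)
        rl = rank_candidates(expr, cohort, "F", "walk400", expr.index, k=30)
        mags = [abs(e.combined_score) for e in rl.entries]
        assert mags == sorted(mags, reverse=True)


class TestRunAll:
    def test_six_strata_on_full_cohort(self, small_expression, small_cohort):
        lists, skipped = run_all(small_expression, small_cohort, small_expression.index, k=10)
        assert len(lists) == 6 and skipped == []
        assert all(len(rl) <= 10 for rl in lists.values())

    def test_single_sex_cohort_skips_other_strata(self, small_expression, small_cohort):
        females = small_cohort[small_cohort["sex"] == "F"]
        lists, skipped = run_all(small_expression, females, small_expression.index, k=10)
        assert set(s for s, _ in lists) == {"F"}
        assert len(skipped) == 3 and all(s == "M" for s, _ in skipped)

    def test_deterministic_given_inputs(self, small_expression, small_cohort):
        l1, _ = run_all(small_expression, small_cohort, small_expression.index, k=5)
        l2, _ = run_all(small_expression, small_cohort, small_expression.index, k=5)
        for key in l1:
            assert l1[key].gene_ids() == l2[key].gene_ids()

    def test_planted_markers_recovered_in_matched_stratum(self, small_expression, small_cohort):
        lists, _ = run_all(small_expression, small_cohort, small_expression.index, k=10)
        assert "MARK_F" in lists[("F", "gait4")].gene_set()
        assert "MARK_M" in lists[("M", "walk400")].gene_set()


class TestEstimatorApi:
    def test_clone_and_params_roundtrip(self):
        est = CorrelationRanker(k=7, score_mode="mean")
        assert clone(est).get_params() == {"k": 7, "score_mode": "mean"}
        est.set_params(k=3)
        assert est.k == 3

    def test_fit_attributes_and_support(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"g{i}" for i in range(8)])
        y = X["g0"] * 0.9 + rng.normal(scale=0.3, size=30)
        est = CorrelationRanker(k=3).fit(X, y)
        assert est.combined_score_.shape == (8,)
        assert est.get_support().sum() <= 3
        assert est.feature_names_in_[est.ranking_[0]] == "g0"
        assert est.transform(X).shape[1] <= 3

    def test_unfitted_raises(self):
        with pytest.raises(Exception):
            CorrelationRanker().top_k()
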