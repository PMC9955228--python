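"""Reliability, correlation, group-difference, ROC and sample-size statistics.

Every statistic is checked against an independent route: a from-first-principles
oracle (hand ANOVA, O(n^2) pair counting, full labeling enumeration) and/or an
established library (pingouin, scipy, scikit-learn, statsmodels).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cranioangle import (
    StatsError,
    absolute_summary,
    icc_3_1,
    mann_whitney_u,
    pearson_r,
    report_markdown,
    roc_analysis,
    run_validation,
    sample_size_t,
    simulate_cohort,
    table1_cohort_spec,
)
from cranioangle.cohort_stats import SchemaError, ValidationSpec


class TestAbsoluteSummary:
    def test_symmetric_pair(self):
        assert absolute_summary([-3, 3]) == (3.0, 0.0)

    def test_hand_arithmetic(self):
        m, s = absolute_summary([-1, 2, -3])
        assert m == pytest.approx(2.0) and s == pytest.approx(1.0)

    def test_singleton_sd_errors(self):
        with pytest.raises(StatsError):
            absolute_summary([0])

    def test_empty_errors(self):
        with pytest.raises(StatsError):
            absolute_summary([])


def _icc31_oracle(X):
    """ICC(3,1) from explicit variance components, written independently."""
    X = np.asarray(X, float)
    n, k = X.shape
    subject_means = X.mean(axis=1)
    rater_means = X.mean(axis=0)
    grand = X.mean()
    ms_rows = k * sum((m - grand) ** 2 for m in subject_means) / (n - 1)
    sse = sum(
        (X[i, j] - subject_means[i] - rater_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_err = sse / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.arange(10.0)
        r = icc_3_1(np.column_stack([x, x]))
        assert r.icc == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        x = rng.normal(5, 3, size=6)
        X = np.column_stack([x, x + rng.normal(0, 1, 6)])
        r = icc_3_1(X)
        assert r.icc == pytest.approx(_icc31_oracle(X), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_oracle_random_matrices(self, rng, k):
        for _ in range(10):
            X = rng.normal(size=(8, k)) + rng.normal(size=(8, 1))
            assert icc_3_1(X).icc == pytest.approx(_icc31_oracle(X), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "y": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        ref_c1 = ref[ref["Type"] == "ICC(C,1)"].iloc[0]  # consistency, single measure
        r = icc_3_1(X)
        assert r.icc == pytest.approx(ref_c1["ICC"], abs=1e-9)
        # pingouin rounds its CI bounds to 2 decimals
        assert r.ci95_low == pytest.approx(ref_c1["CI95"][0], abs=6e-3)
        assert r.ci95_high == pytest.approx(ref_c1["CI95"][1], abs=6e-3)
        assert r.p_value == pytest.approx(ref_c1["pval"], rel=1e-6)
        ref_a1 = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # absolute agreement
        ra = icc_3_1(X, absolute_agreement=True)
        assert ra.icc == pytest.approx(ref_a1["ICC"], abs=1e-9)

    def test_anti_agreement_nonpositive(self, rng):
        x = rng.normal(0, 2, size=8)
        assert icc_3_1(np.column_stack([x, -x])).icc <= 0

    def test_zero_variance_degenerate(self):
        r = icc_3_1(np.ones((5, 2)))
        assert r.icc == 1.0 and r.degenerate

    def test_absolute_agreement_variant_penalizes_offset(self, rng):
        x = rng.normal(10, 3, size=20)
        X = np.column_stack([x, x + 5.0])
        assert icc_3_1(X).icc == pytest.approx(1.0)
        assert icc_3_1(X, absolute_agreement=True).icc < 0.9

    def test_too_small_errors(self):
        with pytest.raises(StatsError):
            icc_3_1(np.ones((2, 2)))


class TestPearson:
    def test_affine_is_one(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.arange(5.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_oracle(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_r(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 9
        assert r == pytest.approx(cov / (x.std(ddof=1) * y.std(ddof=1)), abs=1e-12)

    def test_constant_errors(self):
        with pytest.raises(StatsError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        a = [1.0, 2.0, 3.0]
        u, _ = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_enumerated_example(self):
        """All 6 labelings of {1,2,3,4} into two pairs: exact p = 2/6."""
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_exact_matches_scipy_small_no_ties(self, rng):
        for _ in range(5):
            a, b = rng.normal(size=5), rng.normal(size=6)
            u, p = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(min(ref.statistic, 30 - ref.statistic))
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_vs_normal_approximation_agree(self, rng):
        """Exact enumeration and the tie/continuity-corrected normal p stay close."""
        for _ in range(10):
            a, b = rng.normal(size=6), rng.normal(size=6)
            _, p_exact = mann_whitney_u(a, b)
            p_norm = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_norm) < 0.02

    def test_large_shift_rejects(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(3, 1, 60)
        _, p = mann_whitney_u(a, b)
        assert p < 0.001

    def test_large_sample_matches_scipy_with_ties(self, rng):
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(1, 7, 25).astype(float)
        u, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])


def _auc_oracle(pos, neg):
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sens_at_cutoff == pytest.approx(1.0)
        assert r.spec_at_cutoff == pytest.approx(1.0)

    def test_auc_matches_pair_counting_with_ties(self, rng):
        scores = rng.integers(0, 4, 40).astype(float)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(
            _auc_oracle(scores[labels == 1], scores[labels == 0]), abs=1e-12
        )

    def test_auc_equals_u_over_n1n2(self, rng):
        """Rank-sum duality: AUC = U_greater / (n1 n2), exactly."""
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        pos, neg = scores[labels == 1], scores[labels == 0]
        ranks = stats.rankdata(scores)
        u_greater = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(u_greater / (pos.size * neg.size), abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(1, 2, 80)
        labels = (rng.random(80) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_null_scores_auc_near_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.permutation([0] * 100 + [1] * 100)
        r = roc_analysis(scores, labels)
        assert abs(r.auc - 0.5) < 0.08

    def test_cutoff_balances_sens_and_spec(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)])
        labels = np.array([0] * 60 + [1] * 60)
        r = roc_analysis(scores, labels)
        assert r.sens_at_cutoff == pytest.approx(r.spec_at_cutoff, abs=1e-9)

    def test_monotone_curves(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        r = roc_analysis(scores, labels)
        assert np.all(np.diff(r.sensitivity) <= 0)
        assert np.all(np.diff(r.specificity) >= 0)

    def test_single_class_errors(self):
        with pytest.raises(StatsError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestSampleSize:
    def test_one_tailed_medium_effect(self):
        assert sample_size_t(0.5, 0.05, 0.80, tails=1) == 51

    def test_two_tailed_medium_effect(self):
        assert sample_size_t(0.5, 0.05, 0.80, tails=2) == 64

    def test_large_effect_needs_few(self):
        assert sample_size_t(3.0, 0.05, 0.80, tails=1) <= 4

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        for d, tails, alt in [(0.5, 1, "larger"), (0.5, 2, "two-sided"), (0.8, 2, "two-sided")]:
            n_float = smp.TTestIndPower().solve_power(d, alpha=0.05, power=0.8, alternative=alt)
            assert sample_size_t(d, 0.05, 0.8, tails=tails) == math.ceil(n_float - 1e-9)

    def test_monotonicity(self):
        assert sample_size_t(0.3, 0.05, 0.8) >= sample_size_t(0.5, 0.05, 0.8)
        assert sample_size_t(0.5, 0.01, 0.8) >= sample_size_t(0.5, 0.05, 0.8)
        assert sample_size_t(0.5, 0.05, 0.9) >= sample_size_t(0.5, 0.05, 0.8)

    def test_invalid_arguments(self):
        with pytest.raises(StatsError):
            sample_size_t(-1.0)
        with pytest.raises(StatsError):
            sample_size_t(0.5, alpha=1.5)


class TestRunValidation:
    def test_duplicate_column_perfect_agreement(self, rng):
        coh = simulate_cohort(table1_cohort_spec(seed=3))
        coh["goniometer_2"] = coh["goniometer_1"]
        rep = run_validation(coh)
        assert rep["icc"]["goniometer_1|goniometer_2"]["icc"] == pytest.approx(1.0)
        r, _ = pearson_r(coh["goniometer_1"].abs(), coh["goniometer_2"].abs())
        assert r == pytest.approx(1.0)

    def test_near_identical_raters_high_icc(self, rng):
        coh = simulate_cohort(table1_cohort_spec(seed=5))
        coh["goniometer_2"] = coh["goniometer_1"] + rng.normal(0, 0.05, len(coh))
        rep = run_validation(coh)
        assert rep["icc"]["goniometer_1|goniometer_2"]["icc"] > 0.99

    def test_table1_cohort_typically_rejects_every_column(self):
        """Published effect sizes drive the group test: the median Mann-Whitney
        p over repeated cohorts is far below 0.01 for every measurement."""
        pvals = {}
        for seed in range(15):
            rep = run_validation(simulate_cohort(table1_cohort_spec(seed=seed)))
            for col, r in rep["mann_whitney"].items():
                pvals.setdefault(col, []).append(r["p_value"])
        assert len(pvals) == 7
        for col, ps in pvals.items():
            assert np.median(ps) < 0.01, col

    def test_report_structure_and_markdown(self):
        rep = run_validation(simulate_cohort(table1_cohort_spec(seed=2)))
        assert set(rep) >= {"icc", "pearson", "group_summary", "mann_whitney", "roc"}
        md = report_markdown(rep)
        for heading in ("Reliability", "Correlation", "Mann–Whitney", "ROC"):
            assert heading in md

    def test_single_group_roc_error_entry(self):
        coh = simulate_cohort(table1_cohort_spec(seed=4))
        coh = coh[coh["group"] == "torticollis"].reset_index(drop=True)
        rep = run_validation(coh)
        assert "error" in rep["roc"]

    def test_missing_columns_error(self):
        coh = simulate_cohort(table1_cohort_spec(seed=4)).drop(columns=["still_photo"])
        with pytest.raises(SchemaError, match="still_photo"):
            run_validation(coh)

    def test_duplicate_subject_ids_rejected(self):
        coh = simulate_cohort(table1_cohort_spec(seed=4))
        coh.loc[1, "subject_id"] = coh.loc[0, "subject_id"]
        with pytest.raises(SchemaError, match="unique"):
            run_validation(coh)
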