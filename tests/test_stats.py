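"""Statistics against published table values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hsretina as hs
from hsretina.errors import StatsError
from hsretina.stats import by_fdr, rm_anova_group_effect


class TestTTest:
    def test_mmse_group_difference_table_values(self):
        # cases 23.2 +/- 3.5 (n=15) vs controls 27.8 +/- 1.6 (n=20)
        res = hs.ttest_from_summary(15, 23.2, 3.5, 20, 27.8, 1.6)
        assert res.mean_diff == pytest.approx(4.6)
        assert round(res.ci_low, 1) == 2.8
        assert round(res.ci_high, 1) == 6.4
        assert res.p < 0.0001

    def test_identical_summaries_symmetric_ci(self):
        res = hs.ttest_from_summary(10, 5.0, 1.0, 10, 5.0, 1.0)
        assert res.mean_diff == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        a = hs.ttest_from_summary(12, 1.0, 0.8, 12, 1.5, 0.8, variant="pooled")
        b = hs.ttest_from_summary(12, 1.0, 0.8, 12, 1.5, 0.8, variant="welch")
        assert a.t == pytest.approx(b.t) and a.p == pytest.approx(b.p)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_matches_scipy_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, 2)
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            ours = hs.ttest_from_summary(n1, m1, s1, n2, m2, s2)
            t_ref, p_ref = sps.ttest_ind_from_stats(m2, s2, n2, m1, s1, n1)
            assert ours.t == pytest.approx(t_ref, rel=1e-12)
            assert ours.p == pytest.approx(p_ref, rel=1e-12)

    def test_from_samples_matches_summary_path(self, rng):
        x1, x2 = rng.normal(0, 1, 15), rng.normal(0.5, 1, 20)
        a = hs.ttest_from_samples(x1, x2)
        b = hs.ttest_from_summary(15, x1.mean(), x1.std(ddof=1), 20, x2.mean(), x2.std(ddof=1))
        assert a.t == pytest.approx(b.t)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected_or, expected_hi",
        [
            # male odds, cases(2/13) over controls(7/13)
            ((2, 13, 7, 13), 0.29, 1.64),
            # phakic odds, cases(12/3) over controls(19/1)
            ((12, 3, 19, 1), 0.21, 2.27),
            # no-glaucoma odds, cases(14/1) over controls(18/2)
            ((14, 1, 18, 2), 1.56, 18.96),
            # drusen-present odds, controls(5/15) over cases(3/12)
            ((5, 15, 3, 12), 1.33, 6.74),
        ],
    )
    def test_published_two_by_two_tables(self, cells, expected_or, expected_hi):
        res = hs.odds_ratio_2x2(*cells)
        assert round(res.odds_ratio, 2) == expected_or
        # printed CIs are reproduced to printed precision (the published table's
        # rounding convention differs by <=0.01 on one bound)
        assert res.ci_high == pytest.approx(expected_hi, abs=0.02)

    def test_sex_chi_square_p(self):
        res = hs.odds_ratio_2x2(2, 13, 7, 13)
        assert round(res.p, 2) == 0.15

    def test_unit_table(self):
        assert hs.odds_ratio_2x2(1, 1, 1, 1).odds_ratio == 1.0

    def test_zero_cell_ci_unavailable(self):
        res = hs.odds_ratio_2x2(0, 5, 3, 7)
        assert res.ci_low is None and res.ci_high is None

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 40, 4)
            ours = hs.odds_ratio_2x2(a, b, c, d)
            chi2_ref, p_ref, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert ours.chi2 == pytest.approx(chi2_ref, rel=1e-10)
            assert ours.p == pytest.approx(p_ref, rel=1e-10)
            assert ours.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-12)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert hs.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert hs.pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            hs.pearson_corr(np.ones(10), np.arange(10.0))

    def test_r_and_p_match_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        ours = hs.pearson_corr(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert ours.r == pytest.approx(r_ref, rel=1e-12)
        assert ours.p == pytest.approx(p_ref, rel=1e-9)

    def test_ci_coverage_by_simulation_oracle(self):
        # brute-force check of the Fisher-z interval: over repeated
        # bivariate-normal samples with known rho, the 95% CI must cover
        # rho at its nominal rate
        rho, n, reps = 0.4, 30, 500
        cov = np.array([[1.0, rho], [rho, 1.0]])
        covered = 0
        rng = np.random.default_rng(42)
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = hs.pearson_corr(xy[:, 0], xy[:, 1])
            covered += res.ci_low <= rho <= res.ci_high
        assert abs(covered / reps - 0.95) < 0.03

    def test_p_against_permutation_oracle(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        ours = hs.pearson_corr(x, y)
        perm = np.empty(2000)
        for i in range(2000):
            perm[i] = sps.pearsonr(x, rng.permutation(y))[0]
        p_perm = (np.abs(perm) >= abs(ours.r)).mean()
        assert max(ours.p, p_perm) <= 2 * max(min(ours.p, p_perm), 1 / 2000)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.array(["case"] * 5 + ["control"] * 5)
        res = hs.roc_auc(scores, labels)
        assert res.auc == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_independent_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.array(["case"] * 1000 + ["control"] * 1000)
        assert abs(hs.roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_matches_pairwise_counting_oracle(self, rng):
        for _ in range(100):
            scores = np.round(rng.normal(size=40), 1)  # rounding forces ties
            labels = np.array(["case"] * 20 + ["control"] * 20)
            ours = hs.roc_auc(scores, labels).auc
            case, ctrl = scores[:20], scores[20:]
            total = 0.0
            for cs in case:
                for ks in ctrl:
                    total += 1.0 if cs > ks else (0.5 if cs == ks else 0.0)
            assert ours == pytest.approx(total / 400, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            hs.roc_auc([1.0, 2.0], ["case", "case"])


class TestBenjaminiYekutieli:
    def test_single_hypothesis_reduces_to_plain_threshold(self):
        assert by_fdr([0.04], q=0.05).reject[0]
        assert not by_fdr([0.06], q=0.05).reject[0]

    def test_all_zero_pvalues_all_rejected(self):
        assert by_fdr(np.zeros(7)).reject.all()

    def test_matches_direct_definition_on_random_vectors(self, rng):
        for _ in range(100):
            m = rng.integers(1, 25)
            p = rng.uniform(size=m)
            ours = by_fdr(p, q=0.05).reject
            # brute-force evaluation of the BY definition
            cm = sum(1.0 / j for j in range(1, m + 1))
            order = np.argsort(p)
            i_star = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * 0.05 / (m * cm):
                    i_star = rank
            expected = np.zeros(m, dtype=bool)
            expected[order[:i_star]] = True
            np.testing.assert_array_equal(ours, expected)

    def test_monotone_in_q_and_permutation_invariant(self, rng):
        p = rng.uniform(size=20)
        r1 = by_fdr(p, q=0.05).reject.sum()
        r2 = by_fdr(p, q=0.01).reject.sum()
        assert r2 <= r1
        perm = rng.permutation(20)
        np.testing.assert_array_equal(by_fdr(p[perm]).reject, by_fdr(p).reject[perm])


def score_table(Y, labels):
    rows = []
    for i, (row, lab) in enumerate(zip(Y, labels)):
        for loc, v in zip(hs.LOCATIONS, row):
            rows.append({"subject_id": f"s{i}", "eye": "study", "location_id": loc,
                         "score": v, "label": lab})
    return hs.HSScoreTable(frame=pd.DataFrame(rows))


class TestRmAnova:
    def test_matches_independent_sum_of_squares_oracle(self, rng):
        n1, n2, L = 8, 9, 6
        Y = rng.normal(size=(n1 + n2, L))
        Y[:n1] += 0.8
        labels = ["case"] * n1 + ["control"] * n2
        res = rm_anova_group_effect(score_table(Y, labels))
        # oracle: explicit mixed-design decomposition
        grand = Y.mean()
        mc, mk = Y[:n1].mean(), Y[n1:].mean()
        ss_group = L * (n1 * (mc - grand) ** 2 + n2 * (mk - grand) ** 2)
        subj = Y.mean(axis=1)
        ss_sw = L * (((subj[:n1] - mc) ** 2).sum() + ((subj[n1:] - mk) ** 2).sum())
        F = (ss_group / 1) / (ss_sw / (n1 + n2 - 2))
        assert res.F == pytest.approx(F, rel=1e-10)
        assert (res.df1, res.df2) == (1, n1 + n2 - 2)

    def test_df_convention_for_35_subjects(self, rng):
        Y = rng.normal(size=(35, 6))
        labels = ["case"] * 15 + ["control"] * 20
        res = rm_anova_group_effect(score_table(Y, labels))
        assert (res.df1, res.df2) == (1, 33)

    def test_constant_group_shift_closed_form(self, rng):
        # equal groups shifted by delta with pure between-subject noise
        n, L, delta, sigma = 10, 6, 1.0, 0.3
        subj = rng.normal(0, sigma, 2 * n)
        Y = np.tile(subj[:, None], (1, L)).astype(float)
        Y[:n] += delta
        labels = ["case"] * n + ["control"] * n
        res = rm_anova_group_effect(score_table(Y, labels))
        grand = Y.mean()
        m1, m2 = Y[:n].mean(), Y[n:].mean()
        num = L * (n * (m1 - grand) ** 2 + n * (m2 - grand) ** 2)
        den = L * (((subj[:n] - subj[:n].mean()) ** 2).sum()
                   + ((subj[n:] - subj[n:].mean()) ** 2).sum()) / (2 * n - 2)
        assert res.F == pytest.approx(num / den, rel=1e-10)

    def test_null_calibration(self):
        rejections = 0
        fs = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(20, 6)) + r.normal(size=(20, 1))
            labels = ["case"] * 10 + ["control"] * 10
            res = rm_anova_group_effect(score_table(Y, labels))
            fs.append(res.F)
            rejections += res.p < 0.05
        assert 0.6 < np.mean(fs) < 1.6
        assert 0.01 < rejections / 300 < 0.10

    def test_missing_cell_rejected(self, rng):
        Y = rng.normal(size=(6, 6))
        labels = ["case"] * 3 + ["control"] * 3
        table = score_table(Y, labels)
        table.frame = table.frame.iloc[:-1]
        with pytest.raises(StatsError):
            rm_anova_group_effect(table)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(12, 6))
        Y[:5] += 0.5
        labels = ["case"] * 5 + ["control"] * 7
        table = score_table(Y, labels)
        res = rm_anova_group_effect(table)
        long = table.frame.rename(columns={"location_id": "loc"})
        ref = pg.mixed_anova(data=long, dv="score", within="loc",
                             subject="subject_id", between="label")
        row = ref[ref["Source"] == "label"].iloc[0]
        assert res.F == pytest.approx(row["F"], rel=1e-8)
        assert res.p == pytest.approx(row["p_unc"], rel=1e-6)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_by_rejections_form_step_set_in_sorted_order(pvals):
        """BY rejections are exactly the i* smallest p values."""
        p = np.asarray(pvals)
        res = by_fdr(p, q=0.05)
        order = np.argsort(p, kind="stable")
        sorted_reject = res.reject[order]
        assert res.reject.sum() == res.threshold_index
        if res.threshold_index:
            assert sorted_reject[: res.threshold_index].all()
        assert not sorted_reject[res.threshold_index :].any()
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
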