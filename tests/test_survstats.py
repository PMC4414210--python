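"""Survival statistics: KM, log-rank, concordance, D-index, time-ROC, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirsig.coxph import cox_fit
from mirsig.survstats import (
    bh_fdr,
    concordance,
    d_index,
    km_estimate,
    logrank_test,
    time_dependent_roc,
)


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km.times) == 0
        assert km.survival_at(10) == 1.0

    def test_matches_brute_force_risk_set_product(self):
        rng = np.random.default_rng(20)
        t = rng.exponential(2, size=30).round(1) + 0.1  # force some ties
        e = (rng.random(30) < 0.6).astype(int)
        km = km_estimate(t, e)
        for i, et in enumerate(km.times):
            s = 1.0
            for u in sorted(set(t[(e == 1) & (t <= et)])):
                d = int(((t == u) & (e == 1)).sum())
                n_risk = int((t >= u).sum())
                s *= 1 - d / n_risk
            assert km.survival[i] == pytest.approx(s)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(21)
        km = km_estimate(rng.exponential(1, 50), (rng.random(50) < 0.7).astype(int))
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(22)
        t = rng.exponential(2, 40)
        e = (rng.random(40) < 0.6).astype(int)
        km = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-10)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array(["a"] * 4 + ["b"] * 4)
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy_instance(self):
        # A: times (1,2) events; B: times (3,4) events.  Risk tables:
        # t=1: n=4, nA=2, d=1, E_A=0.5, V=0.25*... hand calculation below
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 1, 1])
        g = np.array(["A", "A", "B", "B"])
        # observed A = 2; expected A = 2/4 + 1/3 + 0 + 0 = 5/6
        # variances: d(n-d)/(n-1) * p(1-p): t=1: 1*3/3*(1/2)(1/2)=1/4
        #            t=2: 1*2/2*(1/3)(2/3)=2/9; later times: nA=0 -> 0
        O_minus_E = 2 - (2 / 4 + 1 / 3)
        V = 1 / 4 + 2 / 9
        expected_chi2 = O_minus_E**2 / V
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(expected_chi2)
        assert p == pytest.approx(float(stats.chi2.sf(expected_chi2, 1)))

    def test_matches_lifelines_multigroup(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(23)
        t = rng.exponential(2, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = rng.choice(["a", "b", "c"], 60)
        chi2, df, p = logrank_test(t, e, g)
        ref = lifelines_stats.multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2, 3, 4, 5])
        scores = -t  # higher score -> earlier event
        assert concordance(scores, t, np.ones(5, int)) == 1.0

    def test_all_tied_scores_give_half(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(24)
        n = 20
        s = rng.normal(size=n)
        t = rng.exponential(1, n).round(1) + 0.1
        e = (rng.random(n) < 0.6).astype(int)
        conc = usable = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                # usable if i fails strictly before j's time, or at equal
                # times with j censored
                if e[i] == 1 and (t[i] < t[j] or (t[i] == t[j] and e[j] == 0)):
                    usable += 1
                    if s[i] > s[j]:
                        conc += 1
                    elif s[i] == s[j]:
                        conc += 0.5
        assert concordance(s, t, e) == pytest.approx(conc / usable)

    def test_matches_lifelines_cindex(self):
        lifelines_utils = pytest.importorskip("lifelines.utils")
        rng = np.random.default_rng(25)
        n = 80
        s = rng.normal(size=n)
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        ours = concordance(s, t, e)
        theirs = lifelines_utils.concordance_index(t, -s, e)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance([1, 2], [1, 1], [0, 0])


class TestDIndex:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(26)
        n = 60
        s = rng.normal(size=n)
        t = np.exp(rng.normal(size=n) - 0.5 * s)
        e = (rng.random(n) < 0.8).astype(int)
        d1 = d_index(s, t, e)
        d2 = d_index(np.exp(3 * s) + 7, t, e)  # strictly monotone transform
        assert d1[0] == pytest.approx(d2[0], rel=1e-10)

    def test_null_scores_give_hr_near_one(self):
        rng = np.random.default_rng(27)
        n = 500
        s = rng.normal(size=n)
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.8).astype(int)
        hr, se, p = d_index(s, t, e)
        assert 0.8 < hr < 1.25

    def test_matches_compositional_oracle_n10(self):
        rng = np.random.default_rng(28)
        n = 10
        s = rng.normal(size=n)
        t = rng.exponential(1, n)
        e = np.ones(n, int)
        hr, se, p = d_index(s, t, e)
        # independent step-by-step pipeline: rank -> Blom -> scale -> Cox
        r = stats.rankdata(s)
        z = stats.norm.ppf((r - 0.375) / (n + 0.25)) / np.sqrt(8 / np.pi)
        fit = cox_fit(z[:, None], t, e)
        assert hr == pytest.approx(float(np.exp(fit.params.iloc[0])))

    def test_all_tied_scores_error(self):
        with pytest.raises(ValueError):
            d_index([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1])


class TestTimeROC:
    def test_perfect_marker_no_censoring(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        s = -t  # higher score = earlier failure
        roc = time_dependent_roc(s, t, np.ones(6, int), [2.5, 4.5])
        np.testing.assert_allclose(roc.auc, 1.0)

    def test_reduces_to_binary_roc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(29)
        n = 150
        s = rng.normal(size=n)
        t = np.exp(rng.normal(size=n) - 0.6 * s)
        e = np.ones(n, int)
        for tau in [0.5, 1.0, 2.0]:
            auc = time_dependent_roc(s, t, e, [tau]).auc[0]
            binary = (t <= tau).astype(int)
            assert auc == pytest.approx(roc_auc_score(binary, s), abs=1e-10)

    def test_eval_time_before_first_event_flagged_nan(self):
        roc = time_dependent_roc([1.0, 2.0], [5.0, 6.0], [1, 1], [1.0, 5.5])
        assert np.isnan(roc.auc[0])
        assert np.isfinite(roc.auc[1])

    def test_auc_bounded(self):
        rng = np.random.default_rng(30)
        n = 100
        s = rng.normal(size=n)
        t = rng.exponential(2, n)
        e = (rng.random(n) < 0.6).astype(int)
        roc = time_dependent_roc(s, t, e, [1, 2, 3])
        finite = roc.auc[np.isfinite(roc.auc)]
        assert ((finite >= 0) & (finite <= 1)).all()


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.04, 0.5]), [0.015, 0.06, 0.5])

    def test_matches_statsmodels(self):
        sm_multitest = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(31)
        p = rng.random(200)
        np.testing.assert_allclose(bh_fdr(p), sm_multitest.multipletests(p, method="fdr_bh")[1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_order(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
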