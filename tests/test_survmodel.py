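"""KM, log-rank, Cox, cutpoint scans and early/late hazard summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qsig import simdata, survmodel as sm


class TestKm:
    def test_no_censoring_steps_and_median(self):
        t = np.arange(1, 11, dtype=float)
        res = sm.km_fit(t, np.ones(10, int))["all"]
        # S drops by 0.1 at each event; median at the 5th event time
        assert np.allclose(np.diff(res.survival[res.survival < 1.0]), -0.1)
        assert res.median == pytest.approx(5.0)

    def test_all_censored_flat_undefined_median(self):
        res = sm.km_fit([3.0, 5.0, 8.0], [0, 0, 0])["all"]
        assert (res.survival == 1.0).all()
        assert not np.isfinite(res.median)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 300)
        res = sm.km_fit(t, np.ones(300, int))["all"]
        emp = 1.0 - np.searchsorted(np.sort(t), res.times, side="right") / 300
        assert np.allclose(res.survival, emp, atol=1e-12)

    def test_exponential_median_closed_form(self, rng):
        lam = 0.03
        t = rng.exponential(1 / lam, 2000)
        res = sm.km_fit(t, np.ones(2000, int))["all"]
        assert abs(res.median - np.log(2) / lam) / (np.log(2) / lam) < 0.05

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            sm.km_fit([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = np.array([2.0, 4, 6, 8, 2, 4, 6, 8])
        e = np.ones(8, int)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = sm.logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_significant(self, rng):
        t = np.concatenate([rng.exponential(1.0, 200),
                            rng.exponential(4.0, 200)])
        g = np.repeat([0, 1], 200)
        _, p = sm.logrank(t, np.ones(400, int), g)
        assert p < 0.001

    def test_six_subject_hand_oracle(self):
        """O-E/V computed by hand over the event table."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        g = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e, var = 0.0, 0.0
        at_risk = list(zip(t, g))
        for ti, gi in sorted(at_risk):
            risk = [x for x in at_risk if x[0] >= ti]
            n, n1 = len(risk), sum(1 for x in risk if x[1] == 1)
            o_minus_e += (gi == 1) - n1 / n
            var += (n1 / n) * (1 - n1 / n) if n > 1 else 0.0
        expected = o_minus_e ** 2 / var
        stat, _ = sm.logrank(t, e, g)
        assert stat == pytest.approx(expected, rel=1e-9)


class TestCox:
    def test_null_covariate_near_zero(self, rng):
        x = rng.normal(size=5000)
        t = rng.exponential(1.0, 5000)
        fit = sm.cox_fit(t, np.ones(5000, int), x)
        assert abs(fit.coef[0]) < 0.1

    def test_two_group_rate_ratio_two(self, rng):
        g = rng.integers(0, 2, 2000)
        t = rng.exponential(1.0 / np.where(g == 1, 2.0, 1.0))
        fit = sm.cox_fit(t, np.ones(2000, int), g.astype(float))
        assert abs(fit.hr[0] - 2.0) < 0.2

    def test_four_subject_grid_search_oracle(self):
        """No ties: coefficient matches brute-force maximisation of the
        hand-written partial likelihood."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 0])
        x = np.array([0.5, -0.2, 1.0, -1.0])

        def pl(b):
            ll = 0.0
            for i in range(4):
                if e[i]:
                    risk = x[t >= t[i]]
                    ll += b * x[i] - np.log(np.sum(np.exp(b * risk)))
            return ll

        grid = np.linspace(-5, 5, 200001)
        best = grid[np.argmax([pl(b) for b in grid])]
        fit = sm.cox_fit(t, e, x)
        assert fit.coef[0] == pytest.approx(best, abs=1e-3)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter
        x = rng.normal(size=250)
        t = np.ceil(rng.exponential(np.exp(-0.5 * x)) * 15)
        e = (rng.random(250) < 0.8).astype(int)
        ours = sm.cox_fit(t, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert ours.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert ours.se[0] == pytest.approx(cph.standard_errors_.iloc[0],
                                           abs=1e-6)

    def test_monotone_time_transform_invariance(self, rng):
        x = rng.normal(size=300)
        t = rng.exponential(np.exp(-0.4 * x))
        e = (rng.random(300) < 0.7).astype(int)
        f1 = sm.cox_fit(t, e, x)
        f2 = sm.cox_fit(np.sqrt(t), e, x)  # strictly monotone transform
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sm.cox_fit([1.0, 2.0, 3.0], [1, 1, 1], np.ones(3))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sm.cox_fit([1.0, 2.0], [0, 0], np.array([1.0, 2.0]))

    def test_separation_flagged_not_raised(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        x = np.array([1.0, 1, 1, 0, 0, 0])  # early deaths all x=1
        fit = sm.cox_fit(t, e, x)
        assert fit.separation


class TestCutpointScan:
    def test_n_minus_one_candidates(self, rng):
        n = 30
        scan = sm.cutpoint_scan(rng.normal(size=n), rng.exponential(5, n),
                                np.ones(n, int))
        assert len(scan.table) == n - 1
        assert list(scan.table["cut_index"]) == list(range(1, n))

    def test_three_subjects_two_cutoffs(self):
        scan = sm.cutpoint_scan([1.0, 2.0, 3.0], [5.0, 3.0, 1.0], [1, 1, 1])
        assert len(scan.table) == 2

    def test_planted_median_step_found_in_middle(self):
        """With a hazard step at the score median, the optimal cut
        concentrates on the middle quintile of ranks (median over seeds)."""
        n = 400
        best = []
        for seed in range(5):
            rng = np.random.default_rng(42 + seed)
            s = rng.normal(size=n)
            high = s > np.median(s)
            t = rng.exponential(1.0 / np.where(high, 2.0, 1.0))
            scan = sm.cutpoint_scan(s, t, np.ones(n, int), min_group=10)
            best.append(scan.best_index)
        assert n * 0.4 <= np.median(best) <= n * 0.6

    def test_null_min_padj_bounded_away_from_zero(self):
        """Permuted scores: no systematic optimal split, so the minimum
        adjusted p stays bounded away from 0 in every seed."""
        mins = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n = 150
            t = rng.exponential(5, n)
            e = (rng.random(n) < 0.8).astype(int)
            scan = sm.cutpoint_scan(rng.normal(size=n), t, e, min_group=5)
            mins.append(scan.table["padj"].min())
        assert min(mins) > 0.01
        assert np.median(mins) > 0.2

    def test_bh_monotone_over_scan(self, rng):
        n = 60
        scan = sm.cutpoint_scan(rng.normal(size=n), rng.exponential(5, n),
                                np.ones(n, int), min_group=3)
        sub = scan.table.dropna().sort_values("p")
        assert (np.diff(sub["padj"]) >= -1e-12).all()

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            sm.cutpoint_scan([1.0, np.nan, 2.0], [1, 2, 3], [1, 1, 1])


class TestDichotomize:
    def test_protective_score_high_group_lives_longer(self):
        rng = np.random.default_rng(3)
        n = 300
        s = rng.normal(size=n)
        t = rng.exponential(np.exp(0.9 * s))  # high score protective
        cohort = pd.DataFrame({"time_months": t, "event": np.ones(n, int),
                               "score": s})
        labels, km, lr, scan = sm.dichotomize_optimal(cohort, "score",
                                                      min_group=20)
        assert km["high"].median > km["low"].median
        assert lr[1] < 0.01

    def test_labels_partition_cohort(self, toy_cohort):
        cohort, _ = toy_cohort
        labels, _, _, _ = sm.dichotomize_optimal(cohort, "gLATE",
                                                 min_group=10)
        assert len(labels) == len(cohort)
        assert set(labels) == {"high", "low"}

    def test_constant_scores_rejected(self):
        cohort = pd.DataFrame({"time_months": [1.0, 2, 3], "event": [1, 1, 1],
                               "score": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="stratification"):
            sm.dichotomize_optimal(cohort, "score")


class TestGeneHazardSummary:
    def test_no_significant_cutpoints_gives_zero(self, rng):
        n = 120
        cohort = pd.DataFrame({
            "time_months": rng.exponential(80, n) + 1,
            "event": (rng.random(n) < 0.7).astype(int),
            "er_status": np.where(rng.random(n) < 0.5, "positive", "negative"),
            "g": rng.normal(size=n)})
        summ = sm.gene_hazard_summary(cohort, "g", min_group=5)
        if summ.n_sig_early == 0:
            assert summ.early_summary == 0.0
        if summ.n_sig_late == 0:
            assert summ.late_summary == 0.0

    def test_late_effect_detected_in_late_window_only(self, toy_cohort):
        cohort, _ = toy_cohort
        late_gene = sm.gene_hazard_summary(cohort, "gLATE")
        null_gene = sm.gene_hazard_summary(cohort, "gNULL")
        assert late_gene.late_summary > late_gene.early_summary
        assert late_gene.n_sig_late > 0
        assert null_gene.n_sig_late == 0

    def test_landmark_separates_windows(self, toy_cohort):
        """Subjects with recurrence before 5 years never enter the late
        window; early-window events all occur at or before the landmark."""
        cohort, _ = toy_cohort
        summ = sm.gene_hazard_summary(cohort, "gLATE", landmark=60.0)
        assert summ.n_late == (cohort["time_months"] > 60.0).sum()
        assert summ.n_early == len(cohort)

    def test_landmark_outside_followup_rejected(self, toy_cohort):
        cohort, _ = toy_cohort
        with pytest.raises(ValueError):
            sm.gene_hazard_summary(cohort, "gLATE",
                                   landmark=cohort["time_months"].max() + 1)

    def test_sign_recovery_across_seeds(self):
        """late summary > early summary when only the late hazard is loaded."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort, _ = simdata.simulate_cohort(
                n_patients=400, beta_early=0.0, beta_late=0.8,
                censor_rate=0.25, seed=600 + seed, genes=["g"],
                prognostic_genes=["g"], gene_loading=0.7)
            summ = sm.gene_hazard_summary(cohort, "g")
            wins += summ.late_summary > summ.early_summary
        assert wins >= 0.9 * n_seeds


class TestCompareEarlyLate:
    def test_exact_small_sample(self):
        stat, p = sm.compare_early_late([3.0, 4.0], [1.0, 2.0])
        assert p == pytest.approx(1 / 3)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = [sm.compare_early_late(rng.normal(size=50),
                                    rng.normal(size=50))[1]
              for _ in range(200)]
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_asymptotic_close_to_exact(self):
        """Exhaustive-enumeration p vs the normal approximation at n=10."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=10), rng.normal(size=10)
        exact = mannwhitneyu(x, y, alternative="two-sided",
                             method="exact").pvalue
        approx = mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            sm.compare_early_late([1.0], [1.0, 2.0])
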