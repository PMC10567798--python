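import numpy as np
import pytest
from scipy.stats import rankdata

from uromir.clinical_validation import (INDETERMINATE, NON_PROGRESSOR,
                                        PROGRESSOR, ckd_epi_egfr,
                                        classify_progression, cox_univariate,
                                        group_compare, invert_ckd_epi,
                                        relative_level, roc_auc, spearman)


class TestRelativeLevel:
    def test_identity(self):
        assert relative_level(25.0, 25.0, 1.0) == pytest.approx(0.0)

    def test_doubling_per_cycle(self):
        # ddCt = -2 -> relative expression 4
        assert relative_level(23.0, 25.0, 1.0) == pytest.approx(np.log10(4))

    def test_log_identity_large_quantity(self):
        ct = 25.0 - np.log2(1e6)
        assert relative_level(ct, 25.0, 1.0) == pytest.approx(6.0)

    def test_reference_pair_mode(self):
        # dCt_sample = 20-15, dCt_cal = 25-18 -> ddCt = -2
        assert relative_level(20.0, 25.0, 1.0, ct_reference=15.0,
                              ct_reference_calibrator=18.0) == pytest.approx(np.log10(4))

    def test_missing_ct_raises(self):
        with pytest.raises(ValueError):
            relative_level(np.nan, 25.0, 1.0)
        with pytest.raises(ValueError):
            relative_level(20.0, 25.0, 0.0)


class TestCkdEpi:
    def test_published_hand_values(self):
        assert ckd_epi_egfr(0.7, 50, "female") == pytest.approx(101.0, abs=1.0)
        assert ckd_epi_egfr(0.9, 40, "male") == pytest.approx(106.5, abs=1.0)

    def test_higher_creatinine_lower_egfr(self):
        lo = ckd_epi_egfr(2.0, 50, "male")
        hi = ckd_epi_egfr(1.0, 50, "male")
        assert lo < hi

    def test_race_term_multiplies(self):
        base = ckd_epi_egfr(1.1, 60, "female")
        assert ckd_epi_egfr(1.1, 60, "female", race_black=True) == pytest.approx(
            base * 1.159)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ckd_epi_egfr(0.0, 50, "female")
        with pytest.raises(ValueError):
            ckd_epi_egfr(1.0, 50, "other")

    @pytest.mark.parametrize("egfr,age,sex", [(30, 70, "male"),
                                              (95, 25, "female"),
                                              (120, 40, "male")])
    def test_inversion_round_trip(self, egfr, age, sex):
        scr = invert_ckd_epi(egfr, age, sex)
        assert ckd_epi_egfr(scr, age, sex) == pytest.approx(egfr, rel=1e-6)


class TestClassifyProgression:
    def test_stable_long_followup_is_non_progressor(self):
        label = classify_progression(100, [(6.0, 95.0)], rrt=False,
                                     followup_years=6.5)
        assert label == NON_PROGRESSOR

    def test_halving_within_five_years_is_progressor(self):
        label = classify_progression(100, [(3.0, 40.0)], rrt=False,
                                     followup_years=4.0)
        assert label == PROGRESSOR

    def test_intermediate_decline_is_indeterminate(self):
        label = classify_progression(100, [(5.0, 70.0)], rrt=False,
                                     followup_years=5.5)
        assert label == INDETERMINATE

    def test_rrt_dominates_stable_trajectory(self):
        label = classify_progression(100, [(6.0, 99.0)], rrt=True,
                                     followup_years=7.0)
        assert label == PROGRESSOR

    def test_empty_trajectory_without_rrt_indeterminate(self):
        assert classify_progression(100, [], rrt=False,
                                    followup_years=8.0) == INDETERMINATE

    def test_late_decline_not_progression(self):
        # halving after the five-year window does not qualify
        label = classify_progression(100, [(6.5, 45.0)], rrt=False,
                                     followup_years=7.0)
        assert label == INDETERMINATE


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3], [2, 4, 6])
        assert rho == pytest.approx(1.0)

    def test_perfect_reverse(self):
        rho, _ = spearman([1, 2, 3], [6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_equals_pearson_on_midranks(self, rng):
        for _ in range(30):
            n = rng.integers(5, 40)
            x = np.round(rng.normal(size=n), 1)  # ties likely
            y = np.round(rng.normal(size=n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_missing_pairs_dropped(self):
        rho, _ = spearman([1, 2, 3, np.nan], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)


class TestGroupCompare:
    def test_exact_two_sample_enumeration(self):
        # U = 0; exact two-sided p = 2/C(6,3) * 1 = 0.1
        stat, p = group_compare([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_near_one(self, rng):
        a = rng.normal(size=40)
        _, p = group_compare(a, a + 0.0)
        assert p > 0.9

    def test_three_group_null_h_statistic_mean(self, rng):
        hs = []
        for _ in range(200):
            groups = [rng.normal(size=40) for _ in range(3)]
            h, _ = group_compare(*groups)
            hs.append(h)
        assert np.mean(hs) == pytest.approx(2.0, abs=0.4)  # chi2, 2 df

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0 and hi == 1.0

    def test_all_tied_scores(self):
        auc, _, _ = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_hand_pair_counting(self):
        auc, _, _ = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_and_u_identity(self, rng):
        from scipy.stats import rankdata
        for _ in range(40):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, lo, hi = roc_auc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = sum(1.0 if p > q else 0.5 if p == q else 0.0
                       for p in pos for q in neg)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)
            ranks = rankdata(scores)
            u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
            assert 0.0 <= lo <= auc <= hi <= 1.0


def breslow_loglik_grid(times, events, x, grid):
    """Independent dense evaluation of the Breslow partial log-likelihood."""
    lls = []
    for beta in grid:
        ll = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = sum(np.exp(beta * x[j]) for j in range(len(times))
                           if times[j] >= times[i])
                ll += beta * x[i] - np.log(risk)
        lls.append(ll)
    return np.asarray(lls)


class TestCoxUnivariate:
    def test_constant_covariate_flagged(self):
        res = cox_univariate([1, 2, 3, 4], [1, 1, 0, 1], [2, 2, 2, 2])
        assert not res.converged and "constant" in res.reason

    def test_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        res = cox_univariate(times, events, x)
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = breslow_loglik_grid(times, events, x, grid)
        assert res.converged
        assert abs(res.beta - grid[np.argmax(lls)]) < 1e-4

    def test_null_covariate_unbiased(self, rng):
        betas = []
        for _ in range(100):
            x = rng.integers(0, 2, 120).astype(float)
            t = rng.exponential(10.0, 120)
            c = rng.exponential(20.0, 120)
            res = cox_univariate(np.minimum(t, c), (t <= c).astype(int), x)
            assert res.converged
            betas.append(res.beta)
        assert abs(np.mean(betas)) < 0.06

    def test_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter
        x = rng.normal(size=80)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.5 * x)))
        c = rng.exponential(8.0, 80)
        to, ev = np.minimum(t, c), (t <= c).astype(int)
        res = cox_univariate(to, ev, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": to, "e": ev, "x": x}), "t", "e")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2], [0, 0], [0.5, 1.5])

    def test_complete_separation_flagged(self):
        # events only in the high-covariate group, perfectly ordered times
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 0, 0, 0]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        res = cox_univariate(times, events, x)
        assert not res.converged
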