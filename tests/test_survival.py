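import numpy as np
import pandas as pd
import pytest

from ppisig.gsva import GsvaProfile
from ppisig.prep import ClinicalTable
from ppisig.survival import (
    bh_adjust,
    chisq_yates,
    fit_cox,
    interaction_screen,
    km_curve,
    logrank_test,
)
from ppisig.synthetic import generate_screen_scenario

from .conftest import toy_clinical
from .oracles import cox_grid_oracle


class TestCox:
    def test_toy_matches_grid_oracle(self):
        # alternating arms: finite maximum (a monotone arrangement separates)
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        cov = [0, 1, 0, 1, 0, 1]
        fit = fit_cox(toy_clinical(times, events, cov), ["x"])
        want = cox_grid_oracle(times, events, cov)
        assert fit.coefficients["x"] == pytest.approx(want, abs=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_toys_match_grid_oracle(self, seed):
        rng = np.random.RandomState(seed)
        n = rng.randint(5, 9)
        times = rng.exponential(1.0, size=n).round(3) + 0.01
        events = np.ones(n, dtype=int)
        cov = rng.normal(size=n).round(2)
        fit = fit_cox(toy_clinical(times, events, cov), ["x"])
        want = cox_grid_oracle(times, events, cov)
        if abs(want) < 7:  # grid oracle unreliable near separation boundary
            assert fit.coefficients["x"] == pytest.approx(want, abs=1e-3)

    def test_mirrored_arms_give_zero_coefficient(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1] * 6
        cov = [0, 0, 0, 1, 1, 1]
        fit = fit_cox(toy_clinical(times, events, cov), ["x"])
        assert abs(fit.coefficients["x"]) < 1e-6

    def test_duplicated_rows_same_beta_smaller_se(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 0, 1, 1, 0]
        cov = [0.2, -1.0, 0.5, 1.5, -0.3, 0.8]
        fit1 = fit_cox(toy_clinical(times, events, cov), ["x"])
        fit2 = fit_cox(toy_clinical(times * 2, events * 2, cov * 2), ["x"])
        # duplication creates event-time ties, so the Efron-corrected
        # estimate moves slightly; it stays close and gains precision
        assert fit2.coefficients["x"] == pytest.approx(
            fit1.coefficients["x"], abs=0.1
        )
        assert fit2.standard_errors["x"] < fit1.standard_errors["x"]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(toy_clinical([1, 2], [0, 0], [0, 1]), ["x"])


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.5]), [0.03, 0.03, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_p(self):
        q = bh_adjust([0.04] * 10)
        assert np.allclose(q, 0.04)

    def test_q_at_least_p_and_rank_monotone(self):
        rng = np.random.RandomState(0)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestKaplanMeier:
    def test_two_events_hand_values(self):
        c = km_curve([1, 2], [1, 1])
        assert c.survival_at(1) == pytest.approx(0.5)
        assert c.survival_at(2) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        c = km_curve([1, 2, 3], [0, 0, 0])
        assert c.survival_at(99) == 1.0

    def test_censoring_hand_values(self):
        # S(1) = 2/3; at t=3 one subject is at risk and dies -> S drops to 0
        c = km_curve([1, 2, 3], [1, 0, 1])
        assert c.survival_at(1) == pytest.approx(2 / 3)
        assert c.survival_at(3) == pytest.approx(0.0)

    def test_censoring_between_events_hand_values(self):
        # 4 subjects: S(1) = 3/4, then censor, then S(3) = 3/4 * 1/2 = 3/8
        c = km_curve([1, 2, 3, 3], [1, 0, 1, 0])
        assert c.survival_at(1) == pytest.approx(3 / 4)
        assert c.survival_at(3) == pytest.approx(3 / 8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [1, 1])

    def test_survival_non_increasing(self):
        rng = np.random.RandomState(1)
        c = km_curve(rng.exponential(1, 50), rng.binomial(1, 0.7, 50))
        assert (np.diff(c.survival) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        res = logrank_test([1, 2, 3], [1, 1, 1], [10, 11, 12], [1, 1, 1])
        assert res.p_value < 0.05

    def test_label_swap_invariance(self):
        ta, ea = [1, 3, 5, 7], [1, 0, 1, 1]
        tb, eb = [2, 4, 6], [1, 1, 0]
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_no_events_at_all(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_early_censored_subject_does_not_move_statistic(self):
        ta, ea = [2.0, 3.0, 4.0], [1, 1, 0]
        tb, eb = [1.5, 2.5, 5.0], [1, 1, 1]
        base = logrank_test(ta, ea, tb, eb).statistic
        with_cens = logrank_test(
            ta + [0.1], ea + [0], tb + [0.1], eb + [0]
        ).statistic
        assert abs(base - with_cens) < 1e-10


class TestChisqYates:
    def test_hand_value(self):
        stat, p = chisq_yates([[10, 20], [20, 10]])
        assert stat == pytest.approx(5.4)

    def test_independence_gives_zero(self):
        stat, p = chisq_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_transpose_invariance(self):
        a = [[3, 11], [9, 5]]
        s1, _ = chisq_yates(a)
        s2, _ = chisq_yates(np.transpose(a))
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_yates([[0, 0], [5, 5]])


class TestInteractionScreen:
    def test_empty_profile_empty_result(self):
        profile = GsvaProfile(pd.DataFrame(np.empty((0, 0))))
        clin = toy_clinical([1, 2], [1, 1], [0, 1])
        res = interaction_screen(profile, clin)
        assert len(res.table) == 0 and res.selected_modules == []

    def test_planted_interaction_detected(self):
        profile, clinical, planted = generate_screen_scenario(
            n_modules=30, n_samples=250, beta_interaction=1.5, seed=11
        )
        res = interaction_screen(profile, clinical)
        assert planted in res.selected_modules

    def test_misaligned_samples_rejected(self):
        profile, clinical, _ = generate_screen_scenario(
            n_modules=3, n_samples=20, seed=0
        )
        clin2 = ClinicalTable(clinical.data.iloc[:-1])
        with pytest.raises(ValueError, match="disagree"):
            interaction_screen(profile, clin2)

    def test_q_at_least_p(self):
        profile, clinical, _ = generate_screen_scenario(
            n_modules=10, n_samples=80, seed=5
        )
        res = interaction_screen(profile, clinical)
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()
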