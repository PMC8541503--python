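import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmrisk import (
    DataValidationError,
    SurvivalData,
    bh_adjust,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    read_survival,
    write_survival,
)

from ._oracles import brute_km, brute_logrank
from .conftest import make_survival


def surv(times, events):
    return SurvivalData([f"s{i}" for i in range(len(times))], times, events)


class TestKM:
    def test_all_censored_flat(self):
        km = km_estimate(surv([3, 5, 9], [0, 0, 0]))
        assert km.event_times.size == 0

    def test_no_censoring_empirical(self):
        km = km_estimate(surv([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit(self):
        # events at 1, 3, 5; censored at 2 and 4
        km = km_estimate(surv([1, 2, 3, 4, 5], [1, 0, 1, 0, 1]))
        np.testing.assert_allclose(km.event_times, [1, 3, 5])
        np.testing.assert_allclose(km.survival, [4 / 5, 8 / 15, 0.0])

    def test_matches_oracle_and_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        s = make_survival(rng, 60, cens_frac=0.3)
        km = km_estimate(s)
        oracle = brute_km(s.time, s.event)
        for t, v in zip(km.event_times, km.survival):
            assert v == pytest.approx(oracle[t])
        kmf = KaplanMeierFitter().fit(s.time, s.event)
        for t, v in zip(km.event_times, km.survival):
            assert v == pytest.approx(kmf.predict(t), abs=1e-10)

    def test_empty_errors(self):
        with pytest.raises(DataValidationError):
            km_estimate(SurvivalData([], [], []))


class TestLogrank:
    def test_identical_groups_null(self):
        s = surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        res = logrank_test(s, [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        s = surv([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        g = np.array([1, 1, 1, 0, 0, 0])
        res = logrank_test(s, g)
        assert res.statistic == pytest.approx(brute_logrank(s.time, s.event, g))

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(11)
        s = make_survival(rng, 80, cens_frac=0.25, eta=0.7 * rng.integers(0, 2, 80))
        g = (rng.random(80) < 0.5).astype(int)
        res = logrank_test(s, g)
        ll = ll_logrank(s.time[g == 1], s.time[g == 0], s.event[g == 1], s.event[g == 0])
        assert res.statistic == pytest.approx(ll.test_statistic)
        assert res.p_value == pytest.approx(ll.p_value)

    def test_label_swap_and_time_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = make_survival(rng, 50, cens_frac=0.3)
        g = (rng.random(50) < 0.4).astype(int)
        base = logrank_test(s, g).statistic
        assert logrank_test(s, 1 - g).statistic == pytest.approx(base)
        warped = SurvivalData(s.sample_ids, np.exp(s.time / s.time.max()), s.event)
        assert logrank_test(warped, g).statistic == pytest.approx(base)

    def test_no_events_flagged(self):
        res = logrank_test(surv([1, 2], [0, 0]), [0, 1])
        assert res.p_value == 1.0 and "no events" in res.note

    def test_empty_group_errors(self):
        with pytest.raises(DataValidationError):
            logrank_test(surv([1, 2], [1, 1]), [1, 1])

    def test_permutation_calibration(self):
        # chi-square(1) reference is calibrated against label shuffling
        rng = np.random.default_rng(42)
        s = make_survival(rng, 30, cens_frac=0.2)
        g = np.array([1] * 15 + [0] * 15)
        crit = stats.chi2.ppf(0.95, 1)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(g)
            if logrank_test(s, g).statistic > crit:
                hits += 1
        assert 0.03 <= hits / n_perm <= 0.07


class TestCox:
    def test_symmetric_groups_zero_beta(self):
        times = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
        events = np.array([1, 0, 1, 1, 0] * 2)
        fit = cox_fit(np.array([0] * 5 + [1] * 5, dtype=float), surv(times, events))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_score_test_equals_logrank_untied(self):
        rng = np.random.default_rng(8)
        s = make_survival(rng, 70, cens_frac=0.3)
        x = rng.integers(0, 2, 70).astype(float)
        st_res = cox_score_test(x, s, ties="breslow")
        lr = logrank_test(s, x.astype(int))
        assert abs(st_res.statistic - lr.statistic) < 1e-8

    def test_hr_recovery(self):
        rng = np.random.default_rng(15)
        x = rng.integers(0, 2, 800).astype(float)
        s = make_survival(rng, 800, cens_frac=0.3, eta=np.log(2.0) * x)
        fit = cox_fit(x, s)
        assert fit.converged
        assert 1.7 < fit.hr[0] < 2.35

    def test_matches_lifelines_multivariate(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        x = rng.normal(size=(150, 3))
        s = make_survival(rng, 150, cens_frac=0.3, eta=x @ [0.5, -0.4, 0.0])
        fit = cox_fit(x, s, ties="efron")
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["t"], df["e"] = s.time, s.event
        cph = CoxPHFitter().fit(df, "t", "e")
        # lifelines' own convergence tolerance dominates the comparison
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=2e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=2e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_flip_covariate_flips_beta(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 60).astype(float)
        s = make_survival(rng, 60, cens_frac=0.2, eta=0.8 * x)
        f1, f2 = cox_fit(x, s), cox_fit(1 - x, s)
        assert f1.beta[0] == pytest.approx(-f2.beta[0], abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_constant_covariate_errors(self):
        with pytest.raises(DataValidationError, match="constant"):
            cox_fit(np.ones(10), make_survival(np.random.default_rng(0), 10))

    def test_separation_flagged_not_raised(self):
        # low covariate dies first, high covariate all censored later
        times = np.concatenate([np.arange(1, 11), np.arange(20, 30)]).astype(float)
        events = np.array([1] * 10 + [0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        fit = cox_fit(x, surv(times, events))
        assert not fit.converged
        assert "separation" in fit.note or "monotone" in fit.note


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_errors(self):
        with pytest.raises(DataValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_order_preservation(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12) and np.all(q <= 1 + 1e-12)
        # adjusted values are monotone in the input ordering
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def test_survival_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    s = make_survival(rng, 12, cens_frac=0.4)
    path = tmp_path / "surv.tsv"
    write_survival(s, path)
    again = read_survival(path)
    assert again.sample_ids == s.sample_ids
    np.testing.assert_allclose(again.time, s.time)
    np.testing.assert_array_equal(again.event, s.event)
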