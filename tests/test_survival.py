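import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnasd.io import ValidationError
from cnasd.survival import (
    binary_td_auc_matrix,
    cox_fit,
    cox_score_gradient,
    km_logrank,
    km_survival_at,
    lr_test,
    td_auc,
)
from conftest import surv_from_lp


def censored_dataset(seed, n=150, p=2, beta=(0.8, -0.5)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    t, e = surv_from_lp(rng, X @ np.asarray(beta)[:p])
    return X, t, e


class TestCoxFit:
    def test_sign_flip_negates_coefficient(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 60).astype(float)
        t, e = surv_from_lp(rng, 0.8 * x)
        a = cox_fit(x, t, e)
        b = cox_fit(-x, t, e)
        assert a.coef.iloc[0] == pytest.approx(-b.coef.iloc[0], abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="non-identifiable"):
            cox_fit(np.zeros(10), np.arange(1, 11.0), np.ones(10, int))

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError, match="zero events"):
            cox_fit(np.arange(10.0), np.arange(1, 11.0), np.zeros(10, int))

    def test_matches_brute_force_partial_likelihood_maximizer(self):
        """8 samples, no ties: Newton solution equals a fine grid search
        over the explicit partial likelihood."""
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, -0.2, 0.9])
        t = np.array([3.0, 5.0, 1.0, 2.5, 4.0, 6.0, 7.0, 8.0])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])

        def pl(beta):
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                if not e[i]:
                    continue
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-3, 3, 60001)
        brute = grid[np.argmax([pl(b) for b in grid])]
        fit = cox_fit(x, t, e)
        assert fit.coef.iloc[0] == pytest.approx(brute, abs=1e-4)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_statsmodels(self, ties):
        import statsmodels.api as sm

        X, t, e = censored_dataset(3)
        t = np.round(t, 1)  # force ties to exercise the correction
        fit = cox_fit(X, t, e, ties=ties)
        res = sm.PHReg(t, X, status=e, ties=ties).fit()
        assert np.allclose(fit.coef.to_numpy(), res.params, atol=1e-6)
        assert np.allclose(fit.se.to_numpy(), res.bse, atol=1e-6)
        assert fit.loglik >= fit.loglik_null

    def test_separation_flagged_not_raised(self):
        # covariate perfectly ordered with event times -> monotone likelihood
        x = np.arange(10.0)
        t = np.arange(1, 11.0)[::-1]
        e = np.ones(10, int)
        fit = cox_fit(x, t, e)
        assert not fit.converged

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(7)
        x = (rng.random(2000) < 0.3).astype(float)
        t, e = surv_from_lp(rng, 1.1 * x)
        fit = cox_fit(x, t, e)
        assert fit.coef.iloc[0] == pytest.approx(1.1, rel=0.10)


class TestScoreGradient:
    def test_matches_finite_difference_of_partial_likelihood(self):
        X, t, e = censored_dataset(5, n=40, p=1)
        s = 0.3 * X[:, 0]
        g = cox_score_gradient(s, t, e)

        def pl(score):
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                if not e[i]:
                    continue
                risk = t >= t[i]
                ll += score[i] - np.log(np.sum(np.exp(score[risk])))
            return ll

        eps = 1e-6
        for i in range(0, 40, 7):
            d = np.zeros_like(s)
            d[i] = eps
            fd = (pl(s + d) - pl(s - d)) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-5)


class TestTdAuc:
    def test_perfect_separation_no_censoring(self):
        r = td_auc([0.9, 0.8, 0.2, 0.1], [1, 2, 10, 11], [1, 1, 1, 1], 5)
        assert r.auc == pytest.approx(1.0, abs=1e-12)
        assert (r.n_cases, r.n_controls) == (2, 2)

    def test_three_of_four_pairs_concordant(self):
        r = td_auc([0.9, 0.2, 0.8, 0.1], [1, 2, 10, 11], [1, 1, 1, 1], 5)
        assert r.auc == pytest.approx(0.75, abs=1e-12)

    def test_constant_marker_gives_half(self):
        r = td_auc(np.ones(6), [1, 2, 3, 10, 11, 12], np.ones(6, int), 5)
        assert r.auc == pytest.approx(0.5, abs=1e-12)

    def test_no_cases_flagged_undefined(self):
        r = td_auc([1.0, 2.0], [10.0, 11.0], [1, 1], horizon=5)
        assert not r.defined and np.isnan(r.auc)

    def test_no_controls_flagged_undefined(self):
        r = td_auc([1.0, 2.0], [1.0, 2.0], [1, 1], horizon=5)
        assert not r.defined

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_no_censoring_equals_concordance(self, seed):
        """With complete follow-up the estimator collapses to the
        Mann-Whitney concordance of marker versus 5-year status."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        t = rng.exponential(5, n)
        t = t[(t < 4.0) | (t > 6.0)]  # keep horizon away from ties with it
        if ((t <= 5).sum() == 0) or ((t > 5).sum() == 0):
            return
        m = np.round(rng.normal(size=len(t)), 1)  # coarse -> marker ties
        r = td_auc(m, t, np.ones(len(t), int), 5.0)
        cases, ctrls = m[t <= 5], m[t > 5]
        num = sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a, b in itertools.product(cases, ctrls)
        )
        assert r.auc == pytest.approx(num / (len(cases) * len(ctrls)),
                                      abs=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_marker_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        m = rng.normal(size=n)
        t, e = surv_from_lp(rng, 0.5 * m)
        a = td_auc(m, t, e, 5.0)
        b = td_auc(np.exp(3 * m) + 7, t, e, 5.0)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_censored_matches_independent_km_oracle(self):
        """Direct-formula oracle: sensitivity/specificity built from
        lifelines' Kaplan-Meier estimates at the horizon."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        n = 120
        m = rng.normal(size=n)
        t, e = surv_from_lp(rng, 0.7 * m, censor_max=6.0)

        def km(tt, ee):
            kmf = KaplanMeierFitter().fit(tt, ee)
            return float(kmf.predict(5.0))

        S = km(t, e)
        pts = [(1.0, 1.0)]
        for c in np.unique(m):
            pos = m > c
            if pos.sum() == 0:
                pts.append((0.0, 0.0))
                continue
            p = pos.mean()
            tp = (1 - km(t[pos], e[pos])) * p / (1 - S)
            fp = 1 - km(t[~pos], e[~pos]) * (1 - p) / S
            pts.append((min(max(fp, 0), 1), min(max(tp, 0), 1)))
        fps, tps = np.array(pts).T
        oracle = float(np.sum((fps[:-1] - fps[1:]) * (tps[:-1] + tps[1:]) / 2))
        r = td_auc(m, t, e, 5.0)
        assert r.auc == pytest.approx(oracle, abs=1e-10)

    def test_binary_matrix_path_agrees_with_scalar_path(self):
        rng = np.random.default_rng(2)
        n = 150
        t, e = surv_from_lp(rng, np.zeros(n))
        M = rng.random((25, n)) < rng.uniform(0.02, 0.5, (25, 1))
        aucs = binary_td_auc_matrix(M, t, e, 5.0)
        for k in range(25):
            r = td_auc(M[k].astype(float), t, e, 5.0)
            if np.isnan(aucs[k]):
                assert M[k].all() or not M[k].any() or not r.defined
            else:
                assert aucs[k] == pytest.approx(r.auc, abs=1e-12)


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 0, 1, 1, 0, 1])
        res = km_logrank(
            np.r_[np.zeros(6), np.ones(6)], np.r_[t, t], np.r_[e, e]
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            km_logrank(np.zeros(5), np.arange(1, 6.0), np.ones(5, int))

    def test_large_hazard_ratio_detected(self):
        rng = np.random.default_rng(1)
        g = (rng.random(500) < 0.5).astype(int)
        t, e = surv_from_lp(rng, np.log(4) * g)
        res = km_logrank(g, t, e)
        assert res.p_value < 0.001
        assert res.df == 1

    def test_km_constant_beyond_last_event(self):
        res = km_logrank(
            [0, 0, 0, 1, 1, 1],
            [1.0, 2.0, 9.0, 1.5, 2.5, 8.0],
            [1, 1, 0, 1, 0, 0],
        )
        curve = res.curves["0"]
        tail = curve[curve.index >= 2.0].to_numpy().ravel()
        assert np.all(tail == tail[0])

    def test_km_survival_at_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t, e = surv_from_lp(rng, np.zeros(80))
        t = np.round(t, 1)
        kmf = KaplanMeierFitter().fit(t, e)
        assert km_survival_at(t, e, 5.0) == pytest.approx(
            float(kmf.predict(5.0)), abs=1e-12
        )


class TestLrTest:
    def test_identical_models_give_unit_p(self):
        X, t, e = censored_dataset(4)
        fit = cox_fit(X, t, e)
        res = lr_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        X, t, e = censored_dataset(4)
        a = cox_fit(pd.DataFrame(X, columns=["a", "b"]), t, e)
        c = cox_fit(pd.DataFrame(X[:, :1], columns=["c"]), t, e)
        with pytest.raises(ValidationError, match="nested"):
            lr_test(c, a)

    def test_statistic_nonnegative_and_informative(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        t, e = surv_from_lp(rng, 0.9 * x)
        noise = rng.normal(size=300)
        nested = cox_fit(pd.DataFrame({"x": x}), t, e)
        full = cox_fit(pd.DataFrame({"x": x, "z": noise}), t, e)
        res = lr_test(nested, full)
        assert res.statistic >= 0 and res.df == 1

    def test_null_p_values_approximately_uniform(self):
        """Adding a pure-noise covariate yields uniform LRT p-values."""
        from scipy import stats

        rng = np.random.default_rng(13)
        ps = []
        for _ in range(80):
            x = rng.normal(size=150)
            t, e = surv_from_lp(rng, 0.5 * x)
            noise = rng.normal(size=150)
            nested = cox_fit(pd.DataFrame({"x": x}), t, e)
            full = cox_fit(pd.DataFrame({"x": x, "z": noise}), t, e)
            ps.append(lr_test(nested, full).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.005
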