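import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnasd.cooccur import (
    BurdenPartitioner,
    _two_group_logrank,
    burden_partition,
    cluster_cnas,
    pair_with_burden_cox,
    regularized_cox_cv,
    stratified_km,
    tuple_features,
)
from cnasd.io import ValidationError
from cnasd.survival import cox_fit
from conftest import surv_from_lp


class TestTupleFeatures:
    @pytest.fixture
    def calls(self):
        return pd.DataFrame(
            {
                "1p_loss": [1, 1, 0, 1],
                "22q_loss": [1, 0, 0, 1],
                "9p_loss": [1, 0, 1, 1],
                "4q_loss": [0, 0, 0, 0],
            },
            index=list("abcd"),
        )

    def test_pairs_need_a_size_dependent_member(self, calls):
        tuples = tuple_features(calls, ["1p_loss", "22q_loss"], order=2,
                                min_prevalence=0.0)
        names = set(tuples.columns)
        assert "1p_loss&9p_loss" in names
        assert "22q_loss&9p_loss" in names
        assert "9p_loss&4q_loss" not in names  # no size-dependent member

    def test_indicator_requires_all_members(self, calls):
        tuples = tuple_features(calls, ["1p_loss"], order=2,
                                min_prevalence=0.0)
        # sample a carries 1p, 22q and 9p: all its pairs are present
        assert tuples.loc["a", "1p_loss&22q_loss"] == 1
        # sample b carries only 1p: every pair indicator is 0
        assert (tuples.loc["b"] == 0).all()

    def test_triplet_count_bounded(self, calls):
        tuples = tuple_features(calls, list(calls.columns), order=3,
                                min_prevalence=0.0)
        assert tuples.shape[1] <= 4  # C(4, 3)

    def test_prevalence_filter_exact(self, calls):
        tuples = tuple_features(calls, ["1p_loss"], order=2,
                                min_prevalence=0.5)
        for col in tuples:
            assert tuples[col].mean() >= 0.5

    def test_empty_size_dependent_set_warns(self, calls, caplog):
        with caplog.at_level("WARNING", logger="cnasd"):
            tuples = tuple_features(calls, [], order=2)
        assert tuples.shape[1] == 0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_indicator_is_product_of_member_calls(self, seed):
        rng = np.random.default_rng(seed)
        calls = pd.DataFrame(
            (rng.random((30, 5)) < 0.5).astype(np.int8),
            columns=[f"f{i}" for i in range(5)],
        )
        tuples = tuple_features(calls, ["f0", "f1"], order=2,
                                min_prevalence=0.0)
        for col in tuples:
            a, b = col.split("&")
            np.testing.assert_array_equal(
                tuples[col].to_numpy(),
                calls[a].to_numpy() * calls[b].to_numpy(),
            )


class TestRegularizedCoxSelector:
    @pytest.fixture(scope="class")
    def strong_signal(self):
        rng = np.random.default_rng(17)
        n = 300
        X = pd.DataFrame(
            (rng.random((n, 12)) < 0.25).astype(float),
            columns=[f"f{i}" for i in range(12)],
        )
        t, e = surv_from_lp(rng, 1.4 * X["f0"].to_numpy())
        return X, t, e

    def test_selects_planted_feature(self, strong_signal):
        X, t, e = strong_signal
        model = regularized_cox_cv(X, t, e, alphas=[1.0], folds=5, seed=0)
        assert "f0" in model.selected_features_

    def test_path_contains_empty_model(self, strong_signal):
        """At the top of the regularization path all coefficients are 0."""
        X, t, e = strong_signal
        model = regularized_cox_cv(X, t, e, alphas=[1.0], folds=5, seed=0)
        per_lambda = model.cv_results_.sort_values("lambda", ascending=False)
        assert per_lambda["nnz"].iloc[0] == 0

    def test_selected_within_one_se_of_best(self, strong_signal):
        X, t, e = strong_signal
        model = regularized_cox_cv(X, t, e, alphas=[1.0], folds=5, seed=0)
        cv = model.cv_results_
        chosen = cv[
            np.isclose(cv["lambda"], model.lambda_)
            & (cv["alpha"] == model.alpha_)
        ].iloc[0]
        best = cv.loc[cv["mean_cindex"].idxmax()]
        assert chosen["mean_cindex"] >= best["mean_cindex"] - best["se_cindex"]

    def test_duplicated_feature_shares_weight_under_elastic_net(self):
        rng = np.random.default_rng(23)
        n = 300
        x = (rng.random(n) < 0.3).astype(float)
        noise = (rng.random((n, 3)) < 0.3).astype(float)
        t, e = surv_from_lp(rng, 1.2 * x)
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        y = Surv.from_arrays(e.astype(bool), t)
        lam = 0.01
        single = CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[lam])
        single.fit(np.column_stack([x, noise]), y)
        dup = CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[lam])
        dup.fit(np.column_stack([x, x, noise]), y)
        c_single = single.coef_[0, 0]
        c_dup = dup.coef_[:2, 0]
        assert np.all(np.abs(c_dup) < abs(c_single))
        assert np.sum(c_dup) == pytest.approx(c_single, rel=0.15)

    def test_unpenalized_lasso_matches_cox_fit(self):
        """alpha=1, lambda -> 0 reproduces the plain Cox solution."""
        rng = np.random.default_rng(29)
        n = 400
        X = rng.normal(size=(n, 3))
        t, e = surv_from_lp(rng, X @ [0.8, -0.4, 0.0])
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-6],
                                     tol=1e-9, max_iter=10**6)
        net.fit(X, Surv.from_arrays(e.astype(bool), t))
        fit = cox_fit(X, t, e, ties="breslow")
        assert np.allclose(net.coef_[:, 0], fit.coef.to_numpy(), atol=1e-3)

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 2)))
        t = np.arange(1, 31.0)
        e = np.r_[np.ones(5, int), np.zeros(25, int)]
        with pytest.raises(ValidationError, match="folds"):
            regularized_cox_cv(X, t, e, folds=10)


class TestStratifiedKm:
    @pytest.fixture
    def pair_cohort(self):
        rng = np.random.default_rng(31)
        n = 400
        a = rng.random(n) < 0.35
        b = rng.random(n) < 0.35
        t, e = surv_from_lp(rng, 0.2 * a + 0.2 * b + 1.2 * (a & b))
        return a, b, t, e

    def test_both_stratum_has_worst_survival(self, pair_cohort):
        from cnasd.survival import km_survival_at

        a, b, t, e = pair_cohort
        res = stratified_km(a, b, t, e)
        assert res.overall.p_value < 0.01
        both = res.labels == "both"
        fives = {
            lab: km_survival_at(t[(res.labels == lab).to_numpy()],
                                e[(res.labels == lab).to_numpy()], 5.0)
            for lab in res.labels.unique()
        }
        assert fives["both"] == min(fives.values())

    def test_empty_both_stratum_rejected(self):
        a = np.array([True, False, False, False])
        b = np.array([False, True, False, False])
        with pytest.raises(ValidationError, match="both"):
            stratified_km(a, b, np.arange(1, 5.0), np.ones(4, int))

    def test_single_stratum_rejected(self):
        a = np.ones(4, bool)
        b = np.ones(4, bool)
        with pytest.raises(ValidationError, match="single"):
            stratified_km(a, b, np.arange(1, 5.0), np.ones(4, int))


class TestPairWithBurdenCox:
    def test_planted_pair_effect_detected_net_of_burden(self):
        rng = np.random.default_rng(37)
        n = 400
        pair = (rng.random(n) < 0.2).astype(float)
        burden = rng.poisson(5, n).astype(float)
        t, e = surv_from_lp(rng, np.log(2.5) * pair + 0.05 * burden)
        fit = pair_with_burden_cox(pair, burden, t, e)
        assert fit.wald_p()["pair"] < 0.05

    def test_burden_only_effect_leaves_pair_null(self):
        rng = np.random.default_rng(41)
        covered = 0
        for _ in range(10):
            n = 300
            pair = (rng.random(n) < 0.2).astype(float)
            burden = rng.poisson(5, n).astype(float) + 2 * pair
            t, e = surv_from_lp(rng, 0.15 * burden)
            fit = pair_with_burden_cox(pair, burden, t, e)
            lo = fit.coef["pair"] - 1.96 * fit.se["pair"]
            hi = fit.coef["pair"] + 1.96 * fit.se["pair"]
            covered += int(lo <= 0 <= hi)
        assert covered >= 8

    def test_constant_burden_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        pair = (rng.random(100) < 0.3).astype(float)
        t, e = surv_from_lp(rng, pair)
        with pytest.warns(UserWarning, match="constant burden"):
            fit = pair_with_burden_cox(pair, np.full(100, 3.0), t, e)
        assert fit.names == ["pair"]

    def test_collinear_pair_rejected(self):
        rng = np.random.default_rng(2)
        pair = (rng.random(100) < 0.3).astype(float)
        t, e = surv_from_lp(rng, pair)
        with pytest.raises(ValidationError, match="collinear"):
            pair_with_burden_cox(pair, 2 * pair + 1, t, e)


class TestClusterCnas:
    @pytest.fixture
    def archetype_calls(self):
        """Three planted prevalence archetypes across burden bins."""
        rng = np.random.default_rng(43)
        n = 600
        burden_driver = rng.integers(0, 10, n)
        calls = {}
        for i in range(3):  # constant-high
            calls[f"high{i}"] = (rng.random(n) < 0.8).astype(np.int8)
        for i in range(3):  # burden-increasing
            calls[f"inc{i}"] = (rng.random(n) < burden_driver / 12).astype(
                np.int8
            )
        for i in range(3):  # rare-flat
            calls[f"rare{i}"] = (rng.random(n) < 0.05).astype(np.int8)
        return pd.DataFrame(calls)

    def test_archetypes_recovered_exactly(self, archetype_calls):
        res = cluster_cnas(archetype_calls, seed=0)
        assert res.n_clusters == 3
        groups = {}
        for feat, lab in res.labels.items():
            groups.setdefault(lab, set()).add(feat[:-1])
        assert sorted(map(len, groups.values())) == [1, 1, 1]

    def test_single_feature_rejected(self):
        with pytest.raises(ValidationError):
            cluster_cnas(pd.DataFrame({"a": [1, 0, 1]}))

    def test_feature_order_invariance(self, archetype_calls):
        res_a = cluster_cnas(archetype_calls, seed=0)
        shuffled = archetype_calls[list(archetype_calls.columns[::-1])]
        res_b = cluster_cnas(shuffled, seed=0)
        for f1 in archetype_calls.columns:
            for f2 in archetype_calls.columns:
                same_a = res_a.labels[f1] == res_a.labels[f2]
                same_b = res_b.labels[f1] == res_b.labels[f2]
                assert same_a == same_b


class TestBurdenPartition:
    def test_two_group_logrank_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        n = 200
        g = rng.random(n) < 0.4
        t, e = surv_from_lp(rng, 0.8 * g)
        t = np.round(t, 1)
        ours = _two_group_logrank(t, e, g)
        ref = logrank_test(t[g], t[~g], e[g], e[~g]).test_statistic
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_recovers_planted_change_point(self):
        rng = np.random.default_rng(47)
        n = 500
        burden = rng.poisson(5, n)
        t, e = surv_from_lp(rng, np.log(4) * (burden >= 5))
        part = burden_partition(burden, t, e)
        assert abs(part.first_split_ - 5) <= 1

    def test_no_split_under_null(self):
        rng = np.random.default_rng(53)
        splits = 0
        for _ in range(10):
            n = 300
            burden = rng.poisson(5, n)
            t, e = surv_from_lp(rng, np.zeros(n))
            part = burden_partition(burden, t, e)
            splits += int(part.n_strata_ > 1)
        assert splits <= 1

    def test_small_sample_yields_single_stratum(self):
        rng = np.random.default_rng(1)
        burden = rng.integers(0, 8, 30)
        t, e = surv_from_lp(rng, np.zeros(30))
        part = BurdenPartitioner(min_leaf=20).fit(burden, (t, e))
        assert part.n_strata_ == 1

    def test_constant_burden_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            burden_partition(np.full(100, 4.0), np.arange(1, 101.0),
                             np.ones(100, int))

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(59)
        n = 300
        burden = rng.poisson(5, n)
        t, e = surv_from_lp(rng, 0.2 * burden)
        part = burden_partition(burden, t, e, min_leaf=40)
        strata = part.predict(burden)
        for s in np.unique(strata):
            assert (strata == s).sum() >= 40
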