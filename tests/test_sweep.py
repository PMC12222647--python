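import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cnasd.io import ValidationError
from cnasd.sweep import (
    SizeDependenceCriteria,
    SizeThresholdOptimizer,
    SweepResult,
    composite_threshold_sweep,
    fdr_at_cutoff,
    null_sd_distribution,
    size_dependent_features,
    sweep_feature,
)
from conftest import surv_from_lp


@pytest.fixture
def planted_fraction_data():
    """Fractions with an effect active only above 25% of the arm."""
    rng = np.random.default_rng(21)
    n = 400
    frac = np.where(rng.random(n) < 0.45, rng.beta(1.0, 2.0, n), 0.0)
    active = frac >= 0.25
    t, e = surv_from_lp(rng, 1.1 * active)
    return frac, t, e, active


class TestSweepFeature:
    def test_absent_feature_all_undefined(self):
        t = np.arange(1, 21.0)
        e = np.ones(20, int)
        res = sweep_feature(np.zeros(20), t, e)
        assert res.all_undefined
        assert res.optimal_threshold is None
        assert np.all(np.isnan(res.auc))

    def test_coarser_step_subsamples_fine_curve(self, planted_fraction_data):
        frac, t, e, _ = planted_fraction_data
        fine = sweep_feature(frac, t, e, step=1)
        coarse = sweep_feature(frac, t, e, step=5)
        sel = np.isin(fine.thresholds, coarse.thresholds)
        np.testing.assert_array_equal(fine.auc[sel], coarse.auc)

    def test_argmax_tie_broken_toward_smallest_threshold(self):
        # fractions in {0, 0.5}: every threshold 1..50 yields the same
        # marker, so the whole plateau ties and 1 must win
        rng = np.random.default_rng(5)
        frac = np.where(rng.random(200) < 0.3, 0.5, 0.0)
        t, e = surv_from_lp(rng, 1.0 * (frac > 0))
        res = sweep_feature(frac, t, e)
        assert res.optimal_threshold == 1

    def test_optimum_near_planted_activation(self, planted_fraction_data):
        frac, t, e, _ = planted_fraction_data
        res = sweep_feature(frac, t, e)
        assert abs(res.optimal_threshold - 25) <= 10
        assert res.sd >= 0.01

    def test_prevalence_is_call_rate_at_optimum(self, planted_fraction_data):
        frac, t, e, _ = planted_fraction_data
        res = sweep_feature(frac, t, e)
        expected = np.mean(frac * 100 >= res.optimal_threshold)
        assert res.prevalence == pytest.approx(expected)


class TestSizeDependenceCriteria:
    @staticmethod
    def _result(max_auc, sd, prevalence):
        return SweepResult(
            feature="f", endpoint="recurrence",
            thresholds=np.arange(1, 100),
            auc=np.full(99, max_auc), optimal_threshold=10,
            max_auc=max_auc, sd=sd, prevalence=prevalence,
        )

    @pytest.mark.parametrize(
        "max_auc, sd, prevalence, expected",
        [
            (0.60, 0.01, 0.025, True),   # every boundary is inclusive
            (0.80, 0.009, 0.50, False),  # SD criterion fails
            (0.80, 0.05, 0.024, False),  # prevalence criterion fails
            (0.599, 0.05, 0.50, False),  # AUC criterion fails
        ],
    )
    def test_boundary_semantics(self, max_auc, sd, prevalence, expected):
        res = self._result(max_auc, sd, prevalence)
        frame = size_dependent_features({"recurrence": [res]})
        assert bool(frame["size_dependent"].iloc[0]) is expected

    def test_or_combined_across_endpoints(self):
        good = self._result(0.70, 0.05, 0.30)
        bad = self._result(0.55, 0.005, 0.30)
        frame = size_dependent_features({"recurrence": [bad], "os": [good]})
        assert bool(frame["size_dependent"].iloc[0])
        assert not bool(frame["flag_recurrence"].iloc[0])
        assert bool(frame["flag_os"].iloc[0])

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValidationError):
            SizeDependenceCriteria(min_prevalence=1.5)


class TestNullSdDistribution:
    @pytest.fixture
    def null_data(self):
        rng = np.random.default_rng(8)
        frac = pd.DataFrame(
            np.where(rng.random((120, 4)) < 0.4, rng.random((120, 4)), 0.0),
            columns=list("abcd"),
        )
        t, e = surv_from_lp(rng, np.zeros(120))
        return frac, t, e

    def test_reproducible_under_seed(self, null_data):
        frac, t, e = null_data
        a = null_sd_distribution(frac, t, e, reps=5, seed=42)
        b = null_sd_distribution(frac, t, e, reps=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_mode_differs_from_permutation(self, null_data):
        frac, t, e = null_data
        a = null_sd_distribution(frac, t, e, mode="permute", reps=3, seed=1)
        b = null_sd_distribution(frac, t, e, mode="bootstrap", reps=3, seed=1)
        assert not np.array_equal(a, b)

    def test_invalid_reps_rejected(self, null_data):
        frac, t, e = null_data
        with pytest.raises(ValidationError):
            null_sd_distribution(frac, t, e, reps=0)

    def test_pooled_size_is_reps_times_features(self, null_data):
        frac, t, e = null_data
        out = null_sd_distribution(frac, t, e, reps=6, seed=0)
        assert len(out) <= 6 * frac.shape[1]
        assert len(out) > 0


class TestFdrAtCutoff:
    def test_cutoff_above_max_gives_zero(self):
        assert fdr_at_cutoff([0.001, 0.002, 0.003], 0.01) == 0.0

    def test_cutoff_at_95th_percentile_gives_five_percent(self):
        nulls = np.arange(1, 101) / 1000.0
        cutoff = np.quantile(nulls, 0.95, method="higher")
        assert fdr_at_cutoff(nulls, cutoff) == pytest.approx(0.05, abs=0.011)

    def test_zero_cutoff_gives_one(self):
        assert fdr_at_cutoff([0.001, 0.02], 0.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fdr_at_cutoff([], 0.01)


class TestCompositeSweep:
    def test_single_feature_reduces_to_univariate_sweep(
        self, planted_fraction_data
    ):
        frac, t, e, _ = planted_fraction_data
        table = composite_threshold_sweep(
            pd.DataFrame({"f": frac}), t, e, step=7
        )
        uni = sweep_feature(frac, t, e, step=7)
        comp = table["auc"].to_numpy()
        both = np.isfinite(comp) & np.isfinite(uni.auc)
        # where the call is positively prognostic the fitted coefficient is
        # positive and the linear predictor is a monotone transform of the
        # call, so the AUCs coincide exactly; where the sign flips, the
        # orientations differ and only approximate complementarity holds
        # (the KM estimator is not exactly flip-symmetric under censoring)
        positive = both & (uni.auc > 0.5)
        assert positive.sum() >= 5
        np.testing.assert_allclose(comp[positive], uni.auc[positive],
                                   atol=1e-12)
        flipped = both & ~positive
        np.testing.assert_allclose(comp[flipped], 1.0 - uni.auc[flipped],
                                   atol=0.02)

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValidationError):
            composite_threshold_sweep(
                pd.DataFrame(index=range(5)), np.arange(1, 6.0),
                np.ones(5, int),
            )

    def test_degenerate_thresholds_marked_undefined(
        self, planted_fraction_data
    ):
        frac, t, e, _ = planted_fraction_data
        table = composite_threshold_sweep(
            pd.DataFrame({"f": frac}), t, e, step=1
        )
        absent = 100.0 * frac.max() < table.index.to_numpy()
        assert np.all(np.isnan(table["auc"].to_numpy()[absent]))


class TestSizeThresholdOptimizer:
    def test_sklearn_params_round_trip(self):
        opt = SizeThresholdOptimizer(step=5, min_auc=0.65)
        cloned = clone(opt)
        assert cloned.get_params()["min_auc"] == 0.65
        cloned.set_params(step=2)
        assert cloned.step == 2

    def test_fit_transform_calls_at_optima(self, planted_fraction_data):
        frac, t, e, _ = planted_fraction_data
        X = pd.DataFrame({"1p_loss": frac})
        opt = SizeThresholdOptimizer().fit(X, {"recurrence": (t, e)})
        calls = opt.transform(X)
        thr = opt.optimal_thresholds_["recurrence"]["1p_loss"]
        np.testing.assert_array_equal(
            calls["1p_loss"].to_numpy(), (frac * 100 >= thr).astype(np.int8)
        )

    def test_deterministic_refit(self, planted_fraction_data):
        frac, t, e, _ = planted_fraction_data
        X = pd.DataFrame({"f": frac})
        a = SizeThresholdOptimizer().fit(X, (t, e))
        b = SizeThresholdOptimizer().fit(X, (t, e))
        np.testing.assert_array_equal(
            a.auc_curves_["endpoint"].to_numpy(),
            b.auc_curves_["endpoint"].to_numpy(),
        )

    def test_transform_before_fit_rejected(self):
        with pytest.raises(ValidationError):
            SizeThresholdOptimizer().transform(pd.DataFrame({"f": [0.1]}))
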