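"""Boosted linear Cox risk score and percentile risk groups.

The booster performs steepest-ascent boosting of the Cox partial
likelihood with a linear base learner: each round evaluates the
partial-likelihood gradient at the current additive score and adds
``rate`` times the corresponding coefficient-space gradient ``X^T g`` to
the coefficient vector. With a single round and unit rate this is exactly
one gradient step from zero. Scores remain linear in the inputs, so the
model is a deterministic linear risk score; risk groups cut the training
score distribution at its 25th and 50th percentiles (linear-interpolation
percentiles, boundary values assigned upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ValidationError
from .survival import cox_fit, cox_score_gradient, lr_test

GROUP_LABELS = ("low", "intermediate", "high")


class BoostedCoxRiskScore(BaseEstimator):
    """Linear gradient-boosted Cox risk score.

    Parameters
    ----------
    rate : learning rate per boosting round (default 0.009).
    rounds : number of boosting rounds (default 2; 0 rounds gives an
        all-zero coefficient vector and a constant score).
    percentiles : training-score percentiles defining the risk groups.

    Attributes
    ----------
    coef_ : Series of additive coefficients over features.
    cutpoints_ : training-score values at the group percentiles.
    """

    def __init__(self, rate: float = 0.009, rounds: int = 2,
                 percentiles: tuple[float, float] = (25.0, 50.0)):
        self.rate = rate
        self.rounds = rounds
        self.percentiles = percentiles

    def fit(self, X, y):
        X = pd.DataFrame(X)
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(int)
        if event.sum() == 0:
            raise ValidationError("cannot boost with zero events")
        Xv = X.to_numpy(dtype=float)
        coef = np.zeros(Xv.shape[1])
        for _ in range(self.rounds):
            score = Xv @ coef
            g = cox_score_gradient(score, time, event)
            coef = coef + self.rate * (Xv.T @ g)
        self.coef_ = pd.Series(coef, index=X.columns)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        train_scores = Xv @ coef
        if len(train_scores) >= 4:
            self.cutpoints_ = np.percentile(
                train_scores, list(self.percentiles)
            )
        else:
            self.cutpoints_ = None
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)[list(self.coef_.index)]
        return X.to_numpy(dtype=float) @ self.coef_.to_numpy()

    def predict_group(self, X) -> np.ndarray:
        if self.cutpoints_ is None:
            raise ValidationError(
                "risk groups need >= 4 training scores to freeze percentiles"
            )
        return assign_groups(self.predict(X), self.cutpoints_)


def assign_groups(scores, cutpoints) -> np.ndarray:
    """Label scores low / intermediate / high against frozen cutpoints.

    Boundary rule: a score exactly at a cutpoint belongs to the upper
    group.
    """
    scores = np.asarray(scores, dtype=float)
    p25, p50 = cutpoints
    if p25 == p50:
        warnings.warn("degenerate score distribution: a single risk group",
                      stacklevel=2)
    labels = np.where(
        scores >= p50, "high", np.where(scores >= p25, "intermediate", "low")
    )
    return labels


def risk_groups(
    scores, training_scores=None, percentiles: tuple[float, float] = (25.0, 50.0)
) -> np.ndarray:
    """Percentile-based risk groups, with cutpoints frozen from the
    training scores (defaults to the scores themselves)."""
    scores = np.asarray(scores, dtype=float)
    train = scores if training_scores is None else np.asarray(
        training_scores, dtype=float
    )
    if len(train) < 4:
        raise ValidationError("need >= 4 training scores for percentiles")
    cutpoints = np.percentile(train, list(percentiles))
    return assign_groups(scores, cutpoints)


def boosted_cox_fit(
    features,
    time,
    event,
    covariates=None,
    rate: float = 0.009,
    rounds: int = 2,
) -> BoostedCoxRiskScore:
    """Fit the boosted linear Cox score on features (plus optional
    covariates)."""
    X = pd.DataFrame(features)
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates, index=X.index)], axis=1)
    return BoostedCoxRiskScore(rate=rate, rounds=rounds).fit(X, (time, event))


@dataclass
class ModelComparison:
    p_augmented_adds: float
    p_baseline_adds: float
    stat_augmented_adds: float
    stat_baseline_adds: float


def _score_of(X, time, event) -> np.ndarray:
    Xf = pd.DataFrame(X)
    keep = Xf.columns[Xf.nunique() > 1]
    if len(keep) == 0:
        return np.zeros(len(Xf))
    fit = cox_fit(Xf[keep], time, event)
    return fit.linear_predictor(Xf[keep])


def compare_models(X_baseline, X_augmented, time, event) -> ModelComparison:
    """Bidirectional likelihood-ratio comparison of two risk models.

    Each model is reduced to its Cox linear predictor; each direction then
    tests whether adding the other model's score improves the fit. A score
    collinear with (or identical to) the reference score contributes a
    zero statistic.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    score_a = _score_of(X_baseline, time, event)
    score_b = _score_of(X_augmented, time, event)

    def direction(base: np.ndarray, extra: np.ndarray) -> tuple[float, float]:
        if np.ptp(base) == 0:
            if np.ptp(extra) == 0:
                return 0.0, 1.0
            nested_ll_fit = cox_fit(pd.DataFrame({"s": extra}), time, event)
            res = lr_test(
                CoxNull(nested_ll_fit.loglik_null, time, event), nested_ll_fit
            )
            return res.statistic, res.p_value
        if np.ptp(extra) == 0 or _collinear(base, extra):
            return 0.0, 1.0
        nested = cox_fit(pd.DataFrame({"base": base}), time, event)
        full = cox_fit(
            pd.DataFrame({"base": base, "extra": extra}), time, event
        )
        res = lr_test(nested, full)
        return res.statistic, res.p_value

    stat_b, p_b = direction(score_a, score_b)  # does augmented add to baseline
    stat_a, p_a = direction(score_b, score_a)
    return ModelComparison(
        p_augmented_adds=p_b,
        p_baseline_adds=p_a,
        stat_augmented_adds=stat_b,
        stat_baseline_adds=stat_a,
    )


def _collinear(a: np.ndarray, b: np.ndarray) -> bool:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(a, b)[0, 1]
    return bool(np.isfinite(r) and abs(r) > 1 - 1e-10)


def CoxNull(loglik_null: float, time, event):
    """A degenerate CoxFit standing for the covariate-free null model."""
    from .survival import CoxFit

    return CoxFit(
        coef=pd.Series(dtype=float),
        se=pd.Series(dtype=float),
        loglik=loglik_null,
        loglik_null=loglik_null,
        n_events=int(np.asarray(event).astype(int).sum()),
        n_samples=len(np.asarray(time)),
        converged=True,
        ties="efron",
    )
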