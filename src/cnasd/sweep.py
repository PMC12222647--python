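"""Size-threshold optimization of prognostic CNA features.

For each (arm, direction) feature the percent-altered fraction is binarized
at every integer size threshold from 1% to 99% of the arm, each binary call
is scored by 5-year time-dependent ROC AUC against a survival endpoint, and
the resulting AUC-versus-threshold curve yields the optimal threshold
(argmax, ties toward the smallest threshold), the curve's standard
deviation, and the call prevalence at the optimum. A feature is
"size-dependent" when, for at least one endpoint, max AUC >= 0.60, AUC SD
>= 0.01 and prevalence at the optimum >= 2.5% (all boundaries inclusive).
The SD cutoff's false-discovery rate is estimated from a permutation or
bootstrap null that scrambles the sample-fraction pairing per feature while
keeping each arm's background fraction distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ValidationError
from .survival import binary_td_auc_matrix, cox_fit, td_auc

logger = logging.getLogger("cnasd")

DEFAULT_THRESHOLDS = np.arange(1, 100, 1)


@dataclass(frozen=True)
class SizeDependenceCriteria:
    """The three size-dependence criteria (all compared with ``>=``)."""

    min_auc: float = 0.60
    min_sd: float = 0.01
    min_prevalence: float = 0.025
    step: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_prevalence < 1):
            raise ValidationError("min_prevalence must lie in (0, 1)")
        if self.min_auc <= 0 or self.min_sd <= 0 or self.step <= 0:
            raise ValidationError("criteria must be positive")


@dataclass
class SweepResult:
    """Per-feature AUC curve over size thresholds for one endpoint."""

    feature: str
    endpoint: str
    thresholds: np.ndarray
    auc: np.ndarray  # NaN where a marker class is empty
    optimal_threshold: int | None
    max_auc: float
    sd: float
    prevalence: float
    all_undefined: bool = False
    horizon: float = 5.0

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.auc)

    def meets_criteria(self, criteria: SizeDependenceCriteria) -> bool:
        return (
            not self.all_undefined
            and np.isfinite(self.max_auc)
            and self.max_auc >= criteria.min_auc
            and np.isfinite(self.sd)
            and self.sd >= criteria.min_sd
            and self.prevalence >= criteria.min_prevalence
        )


def _curve_stats(
    fractions: np.ndarray, thresholds: np.ndarray, aucs: np.ndarray
) -> tuple[int | None, float, float, float]:
    defined = np.isfinite(aucs)
    if not defined.any():
        return None, np.nan, np.nan, np.nan
    best = np.nanmax(aucs)
    # argmax with ties broken toward the smallest threshold
    opt = int(thresholds[np.flatnonzero(defined & (aucs == best))[0]])
    sd = float(np.std(aucs[defined], ddof=1)) if defined.sum() > 1 else np.nan
    prevalence = float(np.mean(fractions * 100.0 >= opt))
    return opt, float(best), sd, prevalence


def sweep_feature(
    fractions,
    time,
    event,
    horizon: float = 5.0,
    step: int = 1,
    feature: str = "feature",
    endpoint: str = "endpoint",
) -> SweepResult:
    """AUC curve of one feature's binary calls across size thresholds."""
    f = np.asarray(fractions, dtype=float)
    thresholds = np.arange(1, 100, step)
    markers = f[None, :] * 100.0 >= thresholds[:, None]
    aucs = binary_td_auc_matrix(markers, time, event, horizon)
    opt, best, sd, prev = _curve_stats(f, thresholds, aucs)
    return SweepResult(
        feature=feature,
        endpoint=endpoint,
        thresholds=thresholds,
        auc=aucs,
        optimal_threshold=opt,
        max_auc=best,
        sd=sd,
        prevalence=prev,
        all_undefined=not np.isfinite(aucs).any(),
        horizon=horizon,
    )


def sweep_all(
    fractions: pd.DataFrame,
    time,
    event,
    horizon: float = 5.0,
    step: int = 1,
    endpoint: str = "endpoint",
) -> list[SweepResult]:
    """Run :func:`sweep_feature` over every column of a fraction table."""
    return [
        sweep_feature(
            fractions[col].to_numpy(),
            time,
            event,
            horizon=horizon,
            step=step,
            feature=col,
            endpoint=endpoint,
        )
        for col in fractions.columns
    ]


def size_dependent_features(
    results_by_endpoint: dict[str, list[SweepResult]],
    criteria: SizeDependenceCriteria = SizeDependenceCriteria(),
) -> pd.DataFrame:
    """Flag features meeting the size-dependence criteria for any endpoint.

    Returns one row per feature with per-endpoint optima, max AUC, SD and
    prevalence, plus per-endpoint and combined (OR across endpoints) flags.
    """
    features: dict[str, dict] = {}
    for endpoint, results in results_by_endpoint.items():
        for res in results:
            row = features.setdefault(res.feature, {"feature": res.feature})
            row[f"opt_{endpoint}"] = res.optimal_threshold
            row[f"max_auc_{endpoint}"] = res.max_auc
            row[f"sd_{endpoint}"] = res.sd
            row[f"prevalence_{endpoint}"] = res.prevalence
            row[f"flag_{endpoint}"] = res.meets_criteria(criteria)
    frame = pd.DataFrame(features.values()).set_index("feature")
    flag_cols = [c for c in frame.columns if c.startswith("flag_")]
    frame["size_dependent"] = frame[flag_cols].any(axis=1)
    return frame


def null_sd_distribution(
    fractions: pd.DataFrame,
    time,
    event,
    mode: str = "permute",
    reps: int = 500,
    seed: int | None = None,
    horizon: float = 5.0,
    step: int = 1,
) -> np.ndarray:
    """Null distribution of the AUC-curve SD under scrambled pairings.

    Per replicate and feature, the sample-to-fraction pairing is permuted
    without replacement (``permute``) or resampled with replacement
    (``bootstrap``) within that feature, keeping each arm's background
    fraction distribution; the sweep is re-run and the SD recorded. The
    pooled (replicate x feature) SDs estimate how often the SD criterion
    fires by chance.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if mode not in ("permute", "bootstrap"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    thresholds = np.arange(1, 100, step)
    out = []
    values = fractions.to_numpy(dtype=float)
    for _ in range(reps):
        for j in range(values.shape[1]):
            col = values[:, j]
            if mode == "permute":
                col = col[rng.permutation(n)]
            else:
                col = col[rng.integers(0, n, size=n)]
            markers = col[None, :] * 100.0 >= thresholds[:, None]
            aucs = binary_td_auc_matrix(markers, time, event, horizon)
            defined = np.isfinite(aucs)
            if defined.sum() > 1:
                out.append(float(np.std(aucs[defined], ddof=1)))
    return np.asarray(out)


def fdr_at_cutoff(null_sds, cutoff: float = 0.01) -> float:
    """Tail proportion of the null SD distribution at the cutoff.

    This per-test false-positive rate is the FDR proxy used to justify the
    SD >= 0.01 criterion.
    """
    null_sds = np.asarray(null_sds, dtype=float)
    if null_sds.size == 0:
        raise ValidationError("empty null distribution")
    return float(np.mean(null_sds >= cutoff))


def composite_threshold_sweep(
    fractions: pd.DataFrame,
    time,
    event,
    covariates: pd.DataFrame | None = None,
    horizon: float = 5.0,
    step: int = 1,
    train_idx=None,
    eval_idx=None,
    ties: str = "efron",
) -> pd.DataFrame:
    """AUC curve of a fixed-membership composite Cox risk score across
    uniform size thresholds.

    At each threshold all member features are re-called, a multivariable
    Cox model on the calls (plus optional covariates) is fit on the
    training indices, and the linear predictor's td-AUC at the horizon is
    evaluated on the evaluation indices. Thresholds where the fit fails or
    every call is constant are undefined.
    """
    if fractions.shape[1] == 0:
        raise ValidationError("composite sweep requires at least one feature")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx)
    eval_idx = np.arange(n) if eval_idx is None else np.asarray(eval_idx)
    thresholds = np.arange(1, 100, step)
    values = fractions.to_numpy(dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    rows = []
    for thr in thresholds:
        calls = (values * 100.0 >= thr).astype(float)
        design = calls if cov is None else np.hstack([calls, cov])
        tr = design[train_idx]
        keep = np.ptp(tr, axis=0) > 0
        auc = np.nan
        if keep.any():
            try:
                fit = cox_fit(tr[:, keep], time[train_idx], event[train_idx],
                              ties=ties)
                if fit.converged:
                    lp = design[eval_idx][:, keep] @ fit.coef.to_numpy()
                    auc = td_auc(lp, time[eval_idx], event[eval_idx], horizon).auc
            except (ValidationError, np.linalg.LinAlgError):
                auc = np.nan
        rows.append({"threshold": int(thr), "auc": auc})
    return pd.DataFrame(rows).set_index("threshold")


class SizeThresholdOptimizer(BaseEstimator, TransformerMixin):
    """Learn per-feature optimal CNA size thresholds from survival data.

    A scikit-learn style transformer: ``fit`` takes a samples x features
    table of percent-altered fractions plus one or more survival endpoints
    and sweeps every feature across size thresholds; ``transform`` emits
    binary CNA calls at each feature's optimal threshold.

    Parameters
    ----------
    horizon : prediction horizon in years for the time-dependent ROC.
    step : threshold step in percent of the arm.
    min_auc, min_sd, min_prevalence : the size-dependence criteria.
    primary_endpoint : endpoint whose optima ``transform`` uses; defaults
        to the first endpoint passed to ``fit``.

    Attributes
    ----------
    results_ : dict endpoint -> list of :class:`SweepResult`.
    auc_curves_ : dict endpoint -> (thresholds x features) DataFrame.
    summary_ : DataFrame of per-feature optima, max AUC, SD, prevalence
        and flags (output of :func:`size_dependent_features`).
    optimal_thresholds_ : dict endpoint -> per-feature threshold Series.
    size_dependent_ : boolean Series over features (OR across endpoints).
    """

    def __init__(
        self,
        horizon: float = 5.0,
        step: int = 1,
        min_auc: float = 0.60,
        min_sd: float = 0.01,
        min_prevalence: float = 0.025,
        primary_endpoint: str | None = None,
    ):
        self.horizon = horizon
        self.step = step
        self.min_auc = min_auc
        self.min_sd = min_sd
        self.min_prevalence = min_prevalence
        self.primary_endpoint = primary_endpoint

    def _criteria(self) -> SizeDependenceCriteria:
        return SizeDependenceCriteria(
            self.min_auc, self.min_sd, self.min_prevalence, self.step
        )

    def fit(self, X, y):
        """``X``: fraction table; ``y``: ``(time, event)`` or a dict
        ``{endpoint name: (time, event)}``."""
        X = pd.DataFrame(X)
        if not isinstance(y, dict):
            y = {"endpoint": y}
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.endpoints_ = list(y)
        self.results_ = {}
        self.auc_curves_ = {}
        self.optimal_thresholds_ = {}
        for endpoint, (time, event) in y.items():
            results = sweep_all(
                X, time, event, horizon=self.horizon, step=self.step,
                endpoint=endpoint,
            )
            self.results_[endpoint] = results
            self.auc_curves_[endpoint] = pd.DataFrame(
                {r.feature: r.auc for r in results},
                index=pd.Index(results[0].thresholds, name="threshold"),
            )
            self.optimal_thresholds_[endpoint] = pd.Series(
                {r.feature: r.optimal_threshold for r in results},
                dtype="object",
            )
        self.summary_ = size_dependent_features(self.results_, self._criteria())
        self.size_dependent_ = self.summary_["size_dependent"]
        return self

    def transform(self, X, endpoint: str | None = None) -> pd.DataFrame:
        """Binary calls at the fitted optimal thresholds (features whose
        optimum is undefined are dropped)."""
        if not hasattr(self, "results_"):
            raise ValidationError("SizeThresholdOptimizer is not fitted")
        endpoint = endpoint or self.primary_endpoint or self.endpoints_[0]
        X = pd.DataFrame(X)
        opts = self.optimal_thresholds_[endpoint].dropna()
        calls = {
            feat: (X[feat].to_numpy(dtype=float) * 100.0 >= thr).astype(np.int8)
            for feat, thr in opts.items()
            if feat in X.columns
        }
        return pd.DataFrame(calls, index=X.index)
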