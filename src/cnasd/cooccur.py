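"""Co-occurrence signatures over size-dependent CNAs.

Builds pair/triplet indicator features (each tuple must contain at least
one size-dependent CNA and be present in >= 2.5% of the cohort), selects
prognostic tuples with cross-validated elastic-net Cox regression under the
1-SE rule, and provides the surrounding survival analyses: 4-way stratified
Kaplan-Meier curves, burden-adjusted bivariate Cox models, unsupervised
clustering of CNA prevalence-by-burden profiles, and recursive-partitioning
strata over CNA burden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError
from .survival import CoxFit, KmLogrankResult, cox_fit, km_logrank

logger = logging.getLogger("cnasd")

MIN_TUPLE_PREVALENCE = 0.025


def default_alpha_grid() -> np.ndarray:
    """Elastic-net mixing grid: 0.05 to 0.95 in 0.05 steps, plus pure
    lasso (1.0)."""
    return np.r_[np.round(np.arange(0.05, 0.96, 0.05), 2), 1.0]


def tuple_features(
    calls: pd.DataFrame,
    size_dependent: list[str],
    order: int = 2,
    min_prevalence: float = MIN_TUPLE_PREVALENCE,
) -> pd.DataFrame:
    """Indicator matrix of CNA tuples with >= 1 size-dependent member.

    ``calls`` holds binary calls at the per-feature optimal thresholds. A
    tuple's indicator is the product of its members' calls; tuples below
    ``min_prevalence`` are dropped. Column names join members with ``&``.
    """
    if order not in (2, 3):
        raise ValidationError("tuple order must be 2 or 3")
    sd = [f for f in size_dependent if f in calls.columns]
    if not sd:
        logger.warning("empty size-dependent set: no tuples emitted")
        return pd.DataFrame(index=calls.index)
    sd_set = set(sd)
    values = calls.to_numpy(dtype=np.int8)
    colidx = {c: i for i, c in enumerate(calls.columns)}
    out = {}
    for combo in combinations(calls.columns, order):
        if not sd_set & set(combo):
            continue
        ind = values[:, [colidx[c] for c in combo]].min(axis=1)
        if ind.mean() >= min_prevalence:
            out["&".join(combo)] = ind
    frame = pd.DataFrame(out, index=calls.index, dtype=np.int8)
    frame.attrs["order"] = order
    frame.attrs["min_prevalence"] = min_prevalence
    return frame


class RegularizedCoxSelector(BaseEstimator):
    """Cross-validated elastic-net Cox feature selection with the 1-SE rule.

    Fits a coordinate-descent penalized Cox model (via scikit-survival's
    Coxnet, Breslow ties) along a regularization path for each mixing value
    ``alpha`` in the grid, scores every (alpha, lambda) by cross-validated
    concordance with event-stratified folds, and selects the sparsest model
    whose mean c-index is within one standard error of the best.

    Attributes
    ----------
    coef_ : Series of selected coefficients (full grid of input features).
    selected_features_ : features with nonzero coefficients.
    alpha_, lambda_ : the selected mixing and penalty strength.
    cv_results_ : DataFrame with one row per (alpha, lambda): mean/SE
        c-index and the number of nonzero coefficients on the full data.
    best_cindex_ : best mean cross-validated c-index.
    """

    def __init__(
        self,
        alphas=None,
        folds: int = 10,
        seed: int | None = 0,
        n_lambdas: int = 50,
        max_iter: int = 100_000,
    ):
        self.alphas = alphas
        self.folds = folds
        self.seed = seed
        self.n_lambdas = n_lambdas
        self.max_iter = max_iter

    def fit(self, X, y):
        """``X``: samples x features; ``y``: ``(time, event)``."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.metrics import concordance_index_censored
        from sksurv.util import Surv

        X = pd.DataFrame(X)
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        n_events = int(event.sum())
        if n_events < 2 * self.folds:
            raise ValidationError(
                f"only {n_events} events for {self.folds}-fold CV; "
                f"reduce the number of folds"
            )
        y_surv = Surv.from_arrays(event, time)
        alphas = (
            default_alpha_grid() if self.alphas is None else np.asarray(self.alphas)
        )
        Xv = X.to_numpy(dtype=float)
        skf = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.seed
        )
        splits = list(skf.split(Xv, event.astype(int)))
        records = []
        full_models = {}
        for a in alphas:
            full = CoxnetSurvivalAnalysis(
                l1_ratio=float(a),
                n_alphas=self.n_lambdas,
                max_iter=self.max_iter,
                fit_baseline_model=False,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full.fit(Xv, y_surv)
            path = np.asarray(full.alphas_)
            full_models[float(a)] = full
            fold_c = np.full((len(splits), len(path)), np.nan)
            for fi, (tr, te) in enumerate(splits):
                model = CoxnetSurvivalAnalysis(
                    l1_ratio=float(a), alphas=path, max_iter=self.max_iter,
                    fit_baseline_model=False,
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(Xv[tr], y_surv[tr])
                except (ValueError, ArithmeticError):
                    continue
                fitted = np.asarray(model.alphas_)
                for li, lam in enumerate(path):
                    if not np.any(np.isclose(fitted, lam)):
                        continue
                    lp = model.predict(Xv[te], alpha=lam)
                    if np.ptp(lp) == 0:
                        fold_c[fi, li] = 0.5
                        continue
                    fold_c[fi, li] = concordance_index_censored(
                        event[te], time[te], lp
                    )[0]
            coefs = full.coef_  # (p, n_lambdas)
            nnz = np.count_nonzero(coefs, axis=0)
            mean_c = np.nanmean(fold_c, axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                se_c = np.nanstd(fold_c, axis=0, ddof=1) / np.sqrt(
                    np.sum(np.isfinite(fold_c), axis=0)
                )
            for li, lam in enumerate(path):
                records.append(
                    {
                        "alpha": float(a),
                        "lambda": float(lam),
                        "mean_cindex": float(mean_c[li]),
                        "se_cindex": float(se_c[li]),
                        "nnz": int(nnz[li]),
                    }
                )
        cv = pd.DataFrame(records)
        cv = cv[np.isfinite(cv["mean_cindex"])]
        if cv.empty:
            raise ValidationError("cross-validation produced no valid models")
        best_i = cv["mean_cindex"].idxmax()
        best = cv.loc[best_i]
        floor = best["mean_cindex"] - best["se_cindex"]
        candidates = cv[cv["mean_cindex"] >= floor]
        # sparsest within 1 SE; ties -> heavier penalty, then smaller alpha
        candidates = candidates.sort_values(
            ["nnz", "lambda", "alpha"], ascending=[True, False, True]
        )
        chosen = candidates.iloc[0]
        self.alpha_ = float(chosen["alpha"])
        self.lambda_ = float(chosen["lambda"])
        full = full_models[self.alpha_]
        li = int(np.argmin(np.abs(np.asarray(full.alphas_) - self.lambda_)))
        coef = full.coef_[:, li]
        self.coef_ = pd.Series(coef, index=X.columns)
        self.selected_features_ = list(self.coef_.index[self.coef_ != 0])
        self.cv_results_ = cv.reset_index(drop=True)
        self.best_cindex_ = float(best["mean_cindex"])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)[list(self.coef_.index)]
        return X.to_numpy(dtype=float) @ self.coef_.to_numpy()


def regularized_cox_cv(
    features: pd.DataFrame,
    time,
    event,
    alphas=None,
    folds: int = 10,
    seed: int | None = 0,
) -> RegularizedCoxSelector:
    """Fit :class:`RegularizedCoxSelector` and return the fitted model."""
    return RegularizedCoxSelector(alphas=alphas, folds=folds, seed=seed).fit(
        features, (time, event)
    )


@dataclass
class StratifiedKmResult:
    labels: pd.Series
    overall: KmLogrankResult
    both_vs_a: float
    both_vs_b: float


def stratified_km(
    calls_a, calls_b, time, event, names: tuple[str, str] = ("A", "B")
) -> StratifiedKmResult:
    """Four-stratum KM analysis of a CNA pair: neither / A only / B only /
    both, with overall and both-vs-single pairwise log-rank tests."""
    from lifelines.statistics import logrank_test

    a = np.asarray(calls_a).astype(bool)
    b = np.asarray(calls_b).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = np.where(
        a & b, "both", np.where(a, f"{names[0]} only",
                                np.where(b, f"{names[1]} only", "neither"))
    )
    if not (a & b).any():
        raise ValidationError("the 'both' stratum is empty")
    if len(np.unique(labels)) < 2:
        raise ValidationError("all samples fall in a single stratum")
    overall = km_logrank(labels, time, event)

    def _pairwise(other: str) -> float:
        m1 = labels == "both"
        m2 = labels == other
        if not m2.any():
            return np.nan
        res = logrank_test(time[m1], time[m2], event[m1], event[m2])
        return float(res.p_value)

    return StratifiedKmResult(
        labels=pd.Series(labels),
        overall=overall,
        both_vs_a=_pairwise(f"{names[0]} only"),
        both_vs_b=_pairwise(f"{names[1]} only"),
    )


def pair_with_burden_cox(pair, burden, time, event) -> CoxFit:
    """Bivariate Cox model of a pair indicator adjusted for CNA burden.

    Falls back to the univariate pair model (with a warning) when burden is
    constant; raises on pair/burden collinearity.
    """
    pair = np.asarray(pair, dtype=float)
    burden = np.asarray(burden, dtype=float)
    if np.ptp(pair) == 0:
        raise ValidationError("pair indicator is constant")
    if np.ptp(burden) == 0:
        warnings.warn(
            "constant burden: falling back to the univariate pair model",
            stacklevel=2,
        )
        return cox_fit(pd.DataFrame({"pair": pair}), time, event)
    if np.allclose(np.corrcoef(pair, burden)[0, 1] ** 2, 1.0):
        raise ValidationError("pair indicator is collinear with burden")
    X = pd.DataFrame({"pair": pair, "burden": burden})
    return cox_fit(X, time, event)


@dataclass
class CnaClusterResult:
    labels: pd.Series
    prevalence: pd.DataFrame  # features x burden bins
    n_clusters: int


def cluster_cnas(
    calls: pd.DataFrame,
    burden: pd.Series | None = None,
    k_range=range(2, 7),
    seed: int = 0,
) -> CnaClusterResult:
    """Cluster CNA features by their prevalence-by-burden profiles.

    Burden bins are the integer burden values top-coded at the 95th
    percentile; the feature x bin prevalence matrix is clustered with Ward
    agglomerative clustering, the number of clusters chosen by the best
    k-means silhouette over ``k_range``.
    """
    if calls.shape[1] < 2:
        raise ValidationError("clustering requires at least 2 features")
    if burden is None:
        burden = calls.sum(axis=1)
    burden = pd.Series(np.asarray(burden), index=calls.index)
    cap = float(np.percentile(burden, 95))
    binned = np.minimum(burden, cap).astype(int)
    prevalence = (
        calls.groupby(binned.to_numpy()).mean().T.sort_index(axis=1)
    )
    prevalence.index.name = "feature"
    if not prevalence.to_numpy().any():
        raise ValidationError("all-zero call matrix")
    Xp = prevalence.to_numpy()
    best_k, best_score = None, -np.inf
    for k in k_range:
        if k >= len(prevalence):
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xp)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(Xp, km.labels_)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        best_k = 2
    agg = AgglomerativeClustering(n_clusters=best_k, linkage="ward").fit(Xp)
    labels = pd.Series(agg.labels_, index=prevalence.index, name="cluster")
    return CnaClusterResult(labels=labels, prevalence=prevalence,
                            n_clusters=best_k)


def _two_group_logrank(time, event, mask) -> float:
    """Two-sample log-rank chi-square statistic (1 df), vectorized."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = mask[order].astype(float)
    n = len(t)
    atrisk = n - np.arange(n)
    atrisk1 = np.cumsum(g[::-1])[::-1]
    # group tied times
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), first)
    d1 = np.add.reduceat(e * g, first)
    n_at = atrisk[first].astype(float)
    n1_at = atrisk1[first]
    use = (d > 0) & (n_at > 1)
    exp1 = d[use] * n1_at[use] / n_at[use]
    var1 = (
        d[use]
        * (n1_at[use] / n_at[use])
        * (1 - n1_at[use] / n_at[use])
        * (n_at[use] - d[use])
        / (n_at[use] - 1)
    )
    O_E = float(np.sum(d1[use] - exp1))
    V = float(np.sum(var1))
    if V <= 0:
        return 0.0
    return O_E**2 / V


class BurdenPartitioner(BaseEstimator):
    """Recursive-partitioning survival strata over CNA burden.

    Greedy binary splits on the burden value maximize the two-sample
    log-rank statistic; a node splits only when both children would hold at
    least ``min_leaf`` samples, the depth is below ``max_depth`` and the
    best split's log-rank p-value is below ``alpha``.

    Attributes
    ----------
    cutpoints_ : sorted burden cutpoints c (strata are ``burden < c1``,
        ``c1 <= burden < c2``, ...).
    n_strata_ : number of leaves.
    """

    def __init__(self, min_leaf: int = 20, max_depth: int = 3,
                 alpha: float = 0.05):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.alpha = alpha

    def fit(self, X, y):
        burden = np.asarray(X, dtype=float).reshape(-1)
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(int)
        if np.ptp(burden) == 0:
            raise ValidationError("burden is constant; nothing to partition")
        cutpoints: list[float] = []
        self.first_split_: float | None = None

        def split(idx: np.ndarray, depth: int) -> None:
            if depth >= self.max_depth or len(idx) < 2 * self.min_leaf:
                return
            b = burden[idx]
            values = np.unique(b)
            best_stat, best_cut = 0.0, None
            n_candidates = 0
            for cut in values[1:]:
                mask = b >= cut
                n1 = int(mask.sum())
                if n1 < self.min_leaf or len(idx) - n1 < self.min_leaf:
                    continue
                n_candidates += 1
                stat = _two_group_logrank(time[idx], event[idx], mask)
                if stat > best_stat:
                    best_stat, best_cut = stat, float(cut)
            if best_cut is None:
                return
            # Bonferroni over the candidate cutpoints: the split statistic
            # is a maximum, so the raw chi-square p is anti-conservative
            p = min(1.0, n_candidates * float(stats.chi2.sf(best_stat, 1)))
            if p >= self.alpha:
                return
            cutpoints.append(best_cut)
            if self.first_split_ is None:
                self.first_split_ = best_cut
            split(idx[burden[idx] < best_cut], depth + 1)
            split(idx[burden[idx] >= best_cut], depth + 1)

        split(np.arange(len(burden)), 0)
        self.cutpoints_ = sorted(cutpoints)
        self.n_strata_ = len(self.cutpoints_) + 1
        self.strata_ = self.predict(burden)
        if self.n_strata_ > 1:
            self.km_ = km_logrank(self.strata_, time, event)
        else:
            self.km_ = None
        return self

    def predict(self, X) -> np.ndarray:
        burden = np.asarray(X, dtype=float).reshape(-1)
        return np.digitize(burden, self.cutpoints_)


def burden_partition(
    burden, time, event, min_leaf: int = 20, max_depth: int = 3
) -> BurdenPartitioner:
    """Fit :class:`BurdenPartitioner` and return the fitted model."""
    return BurdenPartitioner(min_leaf=min_leaf, max_depth=max_depth).fit(
        burden, (time, event)
    )
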